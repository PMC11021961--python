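"""Diagnostic biomarker panels: LASSO selection + logistic regression.

The panel-building procedure mirrors common clinical-biomarker practice:

1. standardize the candidate features and fit an ℓ1-penalized logistic
   regression over a glmnet-style descending lambda grid;
2. choose ``lambda.min`` by stratified 10-fold cross-validated binomial
   deviance and keep the features with nonzero coefficients there;
3. refit an ordinary multivariable logistic regression on the selected
   features, report odds ratios with Wald 95% confidence intervals, and
   reduce the panel to its independent contributors by backward elimination
   at Wald p < 0.05;
4. summarize the final model as a nomogram (per-feature point maps plus a
   total-points → probability table) and an ROC curve with a DeLong
   confidence interval for the AUC.

The module is organised statsmodels-style: :class:`StenosisPanelModel` is
built from a feature table and a contrast, and ``fit`` returns a
:class:`PanelResults` carrying estimates, uncertainties, diagnostics, a
``summary()`` table and plotting helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import CLINICAL_COLUMNS, GROUPS
from .traits import feature_columns

__all__ = [
    "ContrastSpec",
    "StenosisPanelModel",
    "PanelResults",
    "lasso_logistic_path",
    "cv_select_lambda",
    "fit_logistic_wald",
    "roc_auc_delong",
    "make_nomogram",
    "default_contrasts",
    "run_panel_analysis",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Core estimation primitives
# ---------------------------------------------------------------------------

def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100, ratio: float = 1e-3) -> np.ndarray:
    """Descending glmnet-style lambda grid for standardized X.

    ``lambda_max = max |X'(y - mean(y))| / n`` is the smallest penalty that
    zeroes every slope; the grid is log-spaced down to ``ratio * lambda_max``.
    """
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    return np.geomspace(lam_max, ratio * lam_max, n_lambda)


def lasso_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ℓ1-penalized logistic coefficient path over a descending lambda grid.

    ``X`` must be standardized (mean 0, sd 1 per column) with no missing
    cells; the intercept is unpenalized.  The penalty uses the glmnet
    convention: minimize (1/n)·deviance/2 + lambda·‖slopes‖₁.  ``lambda = 0``
    entries are fitted unpenalized.

    Returns ``(lambdas, coefs, intercepts)`` with ``coefs`` of shape
    (n_lambda, n_features).
    """
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0, 1]):
        raise ValueError(f"y must be binary 0/1 with both classes present, got {classes}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant (sd = 0) feature column; drop it before fitting")
    if lambdas is None:
        lambdas = _lambda_grid(X, y)
    lambdas = np.asarray(lambdas, dtype=float)
    n = len(y)
    coefs = np.zeros((len(lambdas), X.shape[1]))
    intercepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        if lam <= 0:
            model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
        else:
            # liblinear objective: ||w||_1 + C * sum log-loss  =>  C = 1/(n*lam)
            model = LogisticRegression(
                l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear",
                max_iter=5000, tol=1e-10, random_state=0,
            )
        model.fit(X, y)
        coefs[i] = model.coef_[0]
        intercepts[i] = model.intercept_[0]
    return lambdas, coefs, intercepts


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
) -> tuple[float, pd.DataFrame]:
    """Select ``lambda.min`` by stratified K-fold cross-validated deviance.

    Fold assignment is reproducible from ``seed``.  If stratification cannot
    place both classes in every training fold the fold count is reduced with
    a warning.  Returns ``(lambda_min, curve)`` where ``curve`` has columns
    ``lambda, mean_deviance, se_deviance, n_nonzero``.
    """
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lambdas is None:
        lambdas = _lambda_grid(X, y)
    n_minority = int(min((y == 0).sum(), (y == 1).sum()))
    if folds > n_minority:
        logger.warning("reducing folds from %d to %d (minority class size)", folds, n_minority)
        folds = n_minority
    if folds < 2:
        raise ValueError("need at least 2 usable folds")
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    deviances = np.zeros((folds, len(lambdas)))
    for k, (train, test) in enumerate(splitter.split(X, y)):
        _, coefs, intercepts = lasso_logistic_path(X[train], y[train], lambdas)
        eta = X[test] @ coefs.T + intercepts
        p = 1.0 / (1.0 + np.exp(-eta))
        for i in range(len(lambdas)):
            deviances[k, i] = _binomial_deviance(y[test], p[:, i])
    mean_dev = deviances.mean(axis=0)
    se_dev = deviances.std(axis=0, ddof=1) / np.sqrt(folds)
    _, full_coefs, _ = lasso_logistic_path(X, y, lambdas)
    curve = pd.DataFrame(
        {
            "lambda": lambdas,
            "mean_deviance": mean_dev,
            "se_deviance": se_dev,
            "n_nonzero": (np.abs(full_coefs) > 1e-10).sum(axis=1),
        }
    )
    lambda_min = float(lambdas[int(np.argmin(mean_dev))])
    return lambda_min, curve


def fit_logistic_wald(
    X: pd.DataFrame,
    y: np.ndarray,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with Wald odds-ratio intervals.

    Fits by Newton-type iteratively reweighted least squares (through
    statsmodels) to tight convergence and returns a table indexed by term
    (``const`` first) with columns ``coef, se, odds_ratio, or_low, or_high,
    p_value``.  Note: forest plots in the source literature label these
    odds ratios "HR"; a logistic model has no hazard scale.

    Raises on rank-deficient design or perfect separation (monotone
    likelihood), advising a penalized fallback.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need n > p for the Wald logistic fit")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])) < X.shape[1] + 1:
        raise ValueError("design matrix is rank deficient (collinear or constant columns)")
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.Logit(y, design)
    try:
        fit = model.fit(method="newton", tol=1e-10, maxiter=200, disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise ValueError(
            "perfect separation detected (monotone likelihood); use a "
            "penalized fit instead"
        ) from exc
    eta = design.to_numpy(dtype=float) @ fit.params
    if not np.all(np.isfinite(fit.bse)) or np.max(np.abs(eta)) > 30:
        # a diverging linear predictor (fitted probabilities numerically 0/1)
        # is the signature of monotone likelihood
        raise ValueError(
            "perfect separation detected (monotone likelihood); use a "
            "penalized fit instead"
        )
    z = stats.norm.ppf(0.5 + conf_level / 2)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "odds_ratio": np.exp(fit.params),
            "or_low": np.exp(fit.params - z * fit.bse),
            "or_high": np.exp(fit.params + z * fit.bse),
            "p_value": fit.pvalues,
        }
    )
    table.index.name = "term"
    return table


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc_delong(
    scores,
    labels,
    conf_level: float = 0.95,
) -> tuple[float, tuple[float, float], pd.DataFrame]:
    """AUC with a DeLong confidence interval and the ROC curve points.

    The AUC is the Mann–Whitney statistic (ties counted one half); its
    variance is estimated from the DeLong placement values ``V10`` (per
    positive) and ``V01`` (per negative), and the normal-theory interval is
    truncated to [0, 1].  Curve points come from ``sklearn.metrics.roc_curve``.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = float((all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n))
    v10 = (all_ranks[:m] - pos_ranks) / n  # placement of each positive
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # placement of each negative
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, ci, curve


# ---------------------------------------------------------------------------
# Nomogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Nomogram:
    """Point-based re-expression of a fitted logistic model.

    Each feature's observed range maps linearly onto a point scale; the
    feature with the largest |coefficient|·range spans exactly 0–100 points.
    ``points(x)`` and ``probability(total_points)`` satisfy the round-trip
    identity: the probability at a sample's total points equals the model
    probability at that sample.
    """

    terms: pd.DataFrame  # index feature: coef, x_ref, x_other, points_max
    intercept: float
    base_linear_predictor: float  # eta at every feature held at its x_ref
    points_unit: float  # linear-predictor increment per nomogram point

    def points(self, x: Mapping[str, float]) -> pd.Series:
        pts = {}
        for feat, row in self.terms.iterrows():
            pts[feat] = row["coef"] * (x[feat] - row["x_ref"]) / self.points_unit
        return pd.Series(pts, name="points")

    def total_points(self, x: Mapping[str, float]) -> float:
        return float(self.points(x).sum())

    def probability(self, total_points: float) -> float:
        eta = self.base_linear_predictor + total_points * self.points_unit
        return float(1.0 / (1.0 + np.exp(-eta)))

    def probability_table(self, n: int = 11) -> pd.DataFrame:
        max_total = float(self.terms["points_max"].sum())
        totals = np.linspace(0.0, max_total, n)
        return pd.DataFrame(
            {"total_points": totals, "probability": [self.probability(t) for t in totals]}
        )


def make_nomogram(
    coef: Mapping[str, float],
    intercept: float,
    feature_ranges: Mapping[str, tuple[float, float]],
) -> Nomogram:
    """Build a nomogram from logistic coefficients and observed ranges.

    For feature i with coefficient β_i over observed range [lo_i, hi_i], the
    reference end ``x_ref`` is the end minimizing β_i·x (so points are always
    non-negative) and ``points_i(x) = 100·|β_i|·(x − x_ref)/max_j(|β_j|·range_j)``.
    """
    rows = []
    for feat, b in coef.items():
        lo, hi = feature_ranges[feat]
        if not np.isfinite([lo, hi]).all() or hi <= lo:
            raise ValueError(f"feature {feat} has a degenerate range [{lo}, {hi}]")
        rows.append((feat, float(b), lo, hi))
    scale = max(abs(b) * (hi - lo) for _, b, lo, hi in rows)
    if scale <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    points_unit = scale / 100.0
    terms = {}
    base_eta = float(intercept)
    for feat, b, lo, hi in rows:
        x_ref, x_other = (lo, hi) if b >= 0 else (hi, lo)
        terms[feat] = {
            "coef": b,
            "x_ref": x_ref,
            "x_other": x_other,
            "points_max": abs(b) * (hi - lo) / points_unit,
        }
        base_eta += b * x_ref
    table = pd.DataFrame.from_dict(terms, orient="index")
    table.index.name = "feature"
    return Nomogram(
        terms=table,
        intercept=float(intercept),
        base_linear_predictor=base_eta,
        points_unit=points_unit,
    )


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContrastSpec:
    """A binary diagnostic contrast over the study groups."""

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...]
    with_clinical: bool = False

    def __post_init__(self) -> None:
        pos, neg = set(self.positive), set(self.negative)
        if not pos or not neg:
            raise ValueError(f"contrast {self.name}: both sides must be nonempty")
        if pos & neg:
            raise ValueError(f"contrast {self.name}: sides overlap: {sorted(pos & neg)}")


#: The headline contrast: any stenosis vs the pooled no-stenosis groups.
STENOSIS_CONTRAST = ContrastSpec(
    name="stenosis",
    positive=("1-CAD", "2-CAD", "3-CAD"),
    negative=("H1", "0-CAD"),
)


def default_contrasts(with_clinical: bool = True) -> list[ContrastSpec]:
    """The five diagnostic contrasts: stenosis vs no-stenosis on glycan
    features, plus one-vs-rest for each stenosis grade within the patient
    groups (each optionally rerun with clinical covariates as candidates)."""
    patient = ("0-CAD", "1-CAD", "2-CAD", "3-CAD")
    contrasts = [STENOSIS_CONTRAST]
    for g in patient:
        rest = tuple(p for p in patient if p != g)
        contrasts.append(ContrastSpec(name=f"{g}_vs_rest", positive=(g,), negative=rest))
        if with_clinical:
            contrasts.append(
                ContrastSpec(
                    name=f"{g}_vs_rest+clinical", positive=(g,), negative=rest,
                    with_clinical=True,
                )
            )
    return contrasts


def _finite_or_none(x: float) -> float | None:
    return float(x) if np.isfinite(x) else None


def penalized_logistic_refit(X: pd.DataFrame, y: np.ndarray, C: float = 1.0) -> pd.DataFrame:
    """Ridge-penalized logistic refit for separated data.

    Fallback when the maximum-likelihood fit diverges (perfect separation):
    coefficients come from an L2-penalized fit on standardized features,
    mapped back to the original scale; Wald standard errors, intervals and
    p-values are undefined under the penalty and reported as NaN.
    """
    from sklearn.linear_model import LogisticRegression

    mean, sd = X.mean(), X.std(ddof=0)
    Xs = (X - mean) / sd
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=5000, tol=1e-10)
    model.fit(Xs.to_numpy(dtype=float), y)
    slopes = model.coef_[0] / sd.to_numpy()
    intercept = model.intercept_[0] - float(np.sum(model.coef_[0] * (mean / sd).to_numpy()))
    params = pd.Series(np.concatenate([[intercept], slopes]), index=["const", *X.columns])
    nan = np.full(len(params), np.nan)
    return pd.DataFrame(
        {
            "coef": params,
            "se": nan,
            "odds_ratio": np.exp(params),
            "or_low": nan,
            "or_high": nan,
            "p_value": nan,
        }
    )


def _drop_collinear(X: pd.DataFrame, selected: Sequence[str], name: str) -> list[str]:
    """Greedily drop later features that are linearly dependent (with the
    intercept) on earlier ones — e.g. complement traits summing to one."""
    kept: list[str] = []
    n = len(X)
    design = np.ones((n, 1))
    for feat in selected:
        candidate = np.column_stack([design, X[feat].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(candidate) == candidate.shape[1]:
            kept.append(feat)
            design = candidate
        else:
            logger.warning("%s: dropping %s (collinear with selected features)", name, feat)
    return kept


class StenosisPanelModel:
    """LASSO + logistic diagnostic panel model for one binary contrast.

    Parameters
    ----------
    X : DataFrame
        Candidate feature matrix (rows = samples).  Rows with missing values
        are dropped (pairwise-complete analysis set).
    y : array-like of {0, 1}
        Binary outcome.
    name : str
        Contrast label carried into results.

    Use :meth:`from_feature_table` to build the model from a pipeline
    feature table and a :class:`ContrastSpec`.
    """

    def __init__(self, X: pd.DataFrame, y, name: str = "panel") -> None:
        X = pd.DataFrame(X).astype(float)
        y = pd.Series(np.asarray(y, dtype=float), index=X.index)
        keep = X.notna().all(axis=1) & y.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.warning("%s: dropping %d sample(s) with missing values", name, dropped)
        X, y = X.loc[keep], y.loc[keep]
        constant = [c for c in X.columns if X[c].std(ddof=0) == 0]
        if constant:
            logger.warning("%s: dropping constant column(s) %s", name, constant)
            X = X.drop(columns=constant)
        if not set(np.unique(y)) == {0.0, 1.0}:
            raise ValueError("y must contain both classes coded 0/1")
        self.X = X
        self.y = y.to_numpy()
        self.name = name

    @classmethod
    def from_feature_table(
        cls,
        table: pd.DataFrame,
        contrast: ContrastSpec,
        candidate_features: Sequence[str] | None = None,
    ) -> "StenosisPanelModel":
        """Build the model for one contrast from a pipeline feature table.

        Rows are restricted to the contrast's groups; candidates default to
        every glycan feature column, plus the clinical covariates
        (age, sex, LDL, HDL, TC) when the contrast requests them.
        """
        if "group" not in table.columns:
            raise ValueError("feature table lacks a 'group' column")
        labels = set(contrast.positive) | set(contrast.negative)
        unknown = labels - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s) in contrast: {sorted(unknown)}")
        sub = table[table["group"].isin(labels)]
        if sub.empty or not set(contrast.positive) & set(sub["group"]):
            raise ValueError(f"contrast {contrast.name}: empty side in the data")
        y = sub["group"].isin(contrast.positive).astype(float)
        if candidate_features is None:
            candidate_features = feature_columns(table)
        cols = list(candidate_features)
        if contrast.with_clinical:
            # TG is omitted from candidates, matching the covariate set
            # conventional for stenosis models (age, sex, LDL, HDL, TC).
            cols += [c for c in ("age", "sex", "ldl", "hdl", "tc") if c in sub.columns]
        return cls(sub[cols], y, name=contrast.name)

    def fit(
        self,
        folds: int = 10,
        seed: int = 0,
        alpha: float = 0.05,
        keep_all_selected_if_none_significant: bool = True,
    ) -> "PanelResults":
        """Run selection + refit + evaluation; returns :class:`PanelResults`.

        ``seed`` fixes the cross-validation fold assignment.  After the
        unpenalized refit on the LASSO-selected features, backward
        elimination at Wald p < ``alpha`` reduces the panel to its
        independent contributors; if no term reaches significance the
        selected set is retained unchanged (flagged in the results).
        """
        Xs = (self.X - self.X.mean()) / self.X.std(ddof=0)
        Xm = Xs.to_numpy()
        lambdas = _lambda_grid(Xm, self.y)
        lambda_min, cv_curve = cv_select_lambda(Xm, self.y, folds=folds, seed=seed, lambdas=lambdas)
        _, coefs, _ = lasso_logistic_path(Xm, self.y, np.array([lambda_min]))
        selected = [c for c, b in zip(self.X.columns, coefs[0]) if abs(b) > 1e-10]
        selected = _drop_collinear(self.X, selected, self.name)
        if not selected:
            # A fully shrunk model: fall back to the single best-correlated
            # candidate so the downstream refit remains defined.
            corr = Xs.apply(lambda col: abs(np.corrcoef(col, self.y)[0, 1]))
            selected = [corr.idxmax()]
            logger.warning("%s: LASSO selected no features; falling back to %s", self.name, selected)
        wald, penalized = self._wald_or_penalized(selected)
        # backward elimination: drop the least significant term and refit
        # until every retained term is individually significant, so the final
        # panel contains only independent contributors
        final, wald_final = list(selected), wald
        while not penalized and len(final) > 1:
            pvals = wald_final.drop("const")["p_value"]
            if pvals.max() < alpha:
                break
            final.remove(pvals.idxmax())
            wald_final, refit_penalized = self._wald_or_penalized(final)
            penalized = penalized or refit_penalized
        none_significant = (
            not penalized and bool((wald_final.drop("const")["p_value"] >= alpha).all())
        )
        if none_significant:
            # a panel with no significant term: retain the selected set whole
            if not keep_all_selected_if_none_significant:
                raise ValueError(f"{self.name}: no selected feature reached p < {alpha}")
            final, wald_final = list(selected), wald
        beta = wald_final["coef"]
        eta = beta["const"] + self.X[final].to_numpy() @ beta.drop("const").to_numpy()
        scores = 1.0 / (1.0 + np.exp(-eta))
        auc, auc_ci, roc_points = roc_auc_delong(scores, self.y)
        ranges = {f: (float(self.X[f].min()), float(self.X[f].max())) for f in final}
        nomogram = make_nomogram(beta.drop("const").to_dict(), float(beta["const"]), ranges)
        full_path_lambdas, full_path_coefs, _ = lasso_logistic_path(Xm, self.y, lambdas)
        return PanelResults(
            model=self,
            name=self.name,
            selected_features=selected,
            final_features=final,
            wald_selected=wald,
            wald=wald_final,
            lambda_min=lambda_min,
            lambda_path=pd.DataFrame(full_path_coefs, index=full_path_lambdas, columns=self.X.columns),
            cv_curve=cv_curve,
            auc=auc,
            auc_ci=auc_ci,
            roc_points=roc_points,
            nomogram=nomogram,
            none_significant=none_significant,
            penalized=penalized,
            seed=seed,
        )

    def _wald_or_penalized(self, features: list[str]) -> tuple[pd.DataFrame, bool]:
        """ML Wald fit, or the documented ridge fallback under separation."""
        try:
            return fit_logistic_wald(self.X[features], self.y), False
        except ValueError as exc:
            if "separation" not in str(exc):
                raise
            logger.warning("%s: %s; using the penalized fallback", self.name, exc)
            return penalized_logistic_refit(self.X[features], self.y), True


@dataclass
class PanelResults:
    """Fitted diagnostic panel: estimates, uncertainty and diagnostics."""

    model: StenosisPanelModel
    name: str
    selected_features: list[str]
    final_features: list[str]
    wald_selected: pd.DataFrame
    wald: pd.DataFrame
    lambda_min: float
    lambda_path: pd.DataFrame
    cv_curve: pd.DataFrame
    auc: float
    auc_ci: tuple[float, float]
    roc_points: pd.DataFrame
    nomogram: Nomogram
    none_significant: bool
    penalized: bool
    seed: int

    @property
    def params(self) -> pd.Series:
        return self.wald["coef"]

    @property
    def odds_ratios(self) -> pd.DataFrame:
        return self.wald.loc[self.wald.index != "const", ["odds_ratio", "or_low", "or_high", "p_value"]]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted stenosis probability for new samples."""
        beta = self.wald["coef"]
        eta = beta["const"] + np.asarray(X[self.final_features], dtype=float) @ beta.drop("const").to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> str:
        lines = [
            f"Diagnostic panel: {self.name}",
            f"  n = {len(self.model.y)} ({int(self.model.y.sum())} positive)",
            f"  candidates = {self.model.X.shape[1]}, lambda.min = {self.lambda_min:.5g}",
            f"  LASSO-selected ({len(self.selected_features)}): {', '.join(self.selected_features)}",
            f"  final panel ({len(self.final_features)}): {', '.join(self.final_features)}"
            + ("  [no term reached Wald significance; selected set retained]" if self.none_significant else "")
            + ("  [ridge fallback: separated data, no Wald inference]" if self.penalized else ""),
            f"  AUC = {self.auc:.3f} (95% CI {self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f}, DeLong)",
            "",
            "  term            OR      95% CI            p",
        ]
        for term, row in self.wald.iterrows():
            if term == "const":
                continue
            lines.append(
                f"  {term:<12} {row['odds_ratio']:>6.2f}  "
                f"[{row['or_low']:.2f}, {row['or_high']:.2f}]  {row['p_value']:.3g}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serializable model artifact."""
        return {
            "contrast": self.name,
            "n": int(len(self.model.y)),
            "selected_features": self.selected_features,
            "final_features": self.final_features,
            "lambda_min": self.lambda_min,
            "coefficients": {t: float(v) for t, v in self.wald["coef"].items()},
            "penalized_fallback": self.penalized,
            "odds_ratios": {
                t: {
                    "or": _finite_or_none(r["odds_ratio"]),
                    "ci": [_finite_or_none(r["or_low"]), _finite_or_none(r["or_high"])],
                    "p": _finite_or_none(r["p_value"]),
                }
                for t, r in self.wald.iterrows()
                if t != "const"
            },
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "nomogram": {
                "points_unit": self.nomogram.points_unit,
                "terms": self.nomogram.terms.reset_index().to_dict(orient="records"),
                "probability_table": self.nomogram.probability_table().to_dict(orient="records"),
            },
            "seed": self.seed,
        }

    def plot_roc(self, ax=None):
        """ROC curve with the AUC and its DeLong interval in the legend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.roc_points["fpr"], self.roc_points["tpr"],
                label=f"AUC {self.auc:.3f} ({self.auc_ci[0]:.3f}-{self.auc_ci[1]:.3f})")
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(self.name)
        ax.legend(loc="lower right")
        return ax

    def plot_path(self, ax=None):
        """LASSO coefficient profiles against log(lambda)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for col in self.lambda_path.columns:
            ax.plot(np.log(self.lambda_path.index), self.lambda_path[col], lw=0.9)
        ax.axvline(np.log(self.lambda_min), ls="--", c="k", lw=0.8)
        ax.set_xlabel("log(lambda)")
        ax.set_ylabel("standardized coefficient")
        ax.set_title(self.name)
        return ax


def run_panel_analysis(
    table: pd.DataFrame,
    contrasts: Sequence[ContrastSpec] | None = None,
    candidate_features: Sequence[str] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, PanelResults]:
    """Fit the diagnostic panels for every contrast.

    By default the five study contrasts are fitted (the four per-grade
    one-vs-rest contrasts each also rerun with clinical covariates among the
    candidates, reporting whether any covariate survives selection).  Each
    contrast consumes a sub-seed derived deterministically from ``seed``.
    """
    if contrasts is None:
        contrasts = default_contrasts(with_clinical="age" in table.columns)
    results: dict[str, PanelResults] = {}
    for i, contrast in enumerate(contrasts):
        model = StenosisPanelModel.from_feature_table(table, contrast, candidate_features)
        res = model.fit(folds=folds, seed=(seed * 1009 + i * 101) % (2**31 - 1))
        if contrast.with_clinical:
            survivors = [f for f in res.final_features if f in CLINICAL_COLUMNS]
            logger.info(
                "%s: clinical covariates in final panel: %s",
                contrast.name, survivors or "none",
            )
        results[contrast.name] = res
    return results
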