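"""Panel modelling: LASSO path, CV, Wald logistic fit, DeLong AUC, nomogram."""

import numpy as np
import pandas as pd
import pytest

from glycopanel.panels import (
    ContrastSpec,
    STENOSIS_CONTRAST,
    StenosisPanelModel,
    _lambda_grid,
    cv_select_lambda,
    fit_logistic_wald,
    lasso_logistic_path,
    make_nomogram,
    roc_auc_delong,
)
from glycopanel.simulate import simulate_panel_cohort


def newton_logistic_mle(X, y, tol=1e-12, maxiter=200):
    """Independent Newton-Raphson oracle for the unpenalized logistic MLE."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(maxiter):
        eta = Xd @ beta
        p = 1 / (1 + np.exp(-eta))
        grad = Xd.T @ (y - p)
        W = p * (1 - p)
        H = Xd.T @ (Xd * W[:, None])
        step = np.linalg.solve(H, grad)
        beta += step
        if np.max(np.abs(grad)) < tol:
            break
    return beta


@pytest.fixture(scope="module")
def logistic_data():
    rng = np.random.default_rng(10)
    X = rng.standard_normal((200, 6))
    X = (X - X.mean(0)) / X.std(0)
    beta = np.array([1.2, -0.8, 0.0, 0.0, 0.0, 0.0])
    p = 1 / (1 + np.exp(-(X @ beta)))
    y = (rng.random(200) < p).astype(float)
    return X, y


class TestLassoPath:
    def test_lambda_max_zeroes_all_slopes(self, logistic_data):
        X, y = logistic_data
        lams, coefs, _ = lasso_logistic_path(X, y)
        assert np.abs(coefs[0]).max() == 0.0
        # and any lambda above lambda_max also gives the null model
        _, coefs2, _ = lasso_logistic_path(X, y, np.array([2 * lams[0]]))
        assert np.abs(coefs2[0]).max() == 0.0

    def test_lambda_zero_matches_newton_mle(self, logistic_data):
        X, y = logistic_data
        _, coefs, intercepts = lasso_logistic_path(X, y, np.array([0.0]))
        oracle = newton_logistic_mle(X, y)
        assert np.abs(intercepts[0] - oracle[0]) < 1e-4
        assert np.abs(coefs[0] - oracle[1:]).max() < 1e-4

    def test_sparsity_decreases_with_lambda(self, logistic_data):
        X, y = logistic_data
        lams, coefs, _ = lasso_logistic_path(X, y)
        nonzero = (np.abs(coefs) > 1e-10).sum(axis=1)
        # descending lambda grid: support sizes non-decreasing up to tolerance
        assert nonzero[0] == 0 and nonzero[-1] >= nonzero[0]
        assert (np.diff(nonzero) >= -1).all()

    def test_informative_features_enter_first(self, logistic_data):
        X, y = logistic_data
        _, coefs, _ = lasso_logistic_path(X, y)
        first_entry = np.argmax(np.abs(coefs) > 1e-10, axis=0).astype(float)
        first_entry[(np.abs(coefs) > 1e-10).sum(axis=0) == 0] = np.inf
        assert set(np.argsort(first_entry)[:2]) == {0, 1}

    def test_constant_column_rejected(self, logistic_data):
        X, y = logistic_data
        bad = X.copy()
        bad[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            lasso_logistic_path(bad, y)

    def test_non_binary_outcome_rejected(self, logistic_data):
        X, _ = logistic_data
        with pytest.raises(ValueError, match="binary"):
            lasso_logistic_path(X, np.arange(len(X), dtype=float))


class TestCvSelectLambda:
    def test_same_seed_reproduces_lambda_min(self, logistic_data):
        X, y = logistic_data
        lam1, _ = cv_select_lambda(X, y, seed=3)
        lam2, _ = cv_select_lambda(X, y, seed=3)
        assert lam1 == lam2

    def test_null_design_selects_sparse_models(self):
        rng = np.random.default_rng(11)
        picks = []
        for seed in range(10):
            X = rng.standard_normal((80, 10))
            X = (X - X.mean(0)) / X.std(0)
            y = (rng.random(80) < 0.5).astype(float)
            lam, _ = cv_select_lambda(X, y, seed=seed)
            _, coefs, _ = lasso_logistic_path(X, y, np.array([lam]))
            picks.append((np.abs(coefs[0]) > 1e-10).sum())
        assert np.median(picks) <= 1

    def test_strong_signal_retains_planted_features(self, logistic_data):
        X, y = logistic_data
        hits = 0
        for seed in range(10):
            lam, _ = cv_select_lambda(X, y, seed=seed)
            _, coefs, _ = lasso_logistic_path(X, y, np.array([lam]))
            if abs(coefs[0][0]) > 1e-10 and abs(coefs[0][1]) > 1e-10:
                hits += 1
        assert hits >= 9

    def test_fold_reduction_warns_on_tiny_minority(self, logistic_data, caplog):
        X, y = logistic_data
        keep = np.concatenate([np.flatnonzero(y == 1)[:4], np.flatnonzero(y == 0)])
        with caplog.at_level("WARNING"):
            cv_select_lambda(X[keep], y[keep], folds=10, seed=0)
        assert any("reducing folds" in r.message for r in caplog.records)


class TestWaldLogistic:
    def test_two_by_two_odds_ratio_closed_form(self):
        # 100 unexposed with 20 events, 100 exposed with 50 events:
        # OR = (50*80)/(50*20) = 4
        x = np.repeat([0.0, 1.0], 100)
        y = np.concatenate([np.repeat([1.0, 0.0], [20, 80]), np.repeat([1.0, 0.0], [50, 50])])
        table = fit_logistic_wald(pd.DataFrame({"exposure": x}), y)
        row = table.loc["exposure"]
        assert row["odds_ratio"] == pytest.approx(4.0, rel=1e-6)
        assert row["or_low"] < 4.0 < row["or_high"]

    def test_all_zero_predictor_rejected(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame({"a": rng.normal(size=50), "b": np.zeros(50)})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic_wald(X, y)

    def test_perfect_separation_raises_with_advice(self):
        x = np.concatenate([np.linspace(-3, -1, 20), np.linspace(1, 3, 20)])
        y = np.repeat([0.0, 1.0], 20)
        with pytest.raises(ValueError, match="separation"):
            fit_logistic_wald(pd.DataFrame({"x": x}), y)

    def test_null_coefficient_ci_coverage(self):
        """Wald CI for a null predictor covers OR=1 at ~95%."""
        rng = np.random.default_rng(13)
        covered = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=120)
            y = (rng.random(120) < 0.5).astype(float)
            row = fit_logistic_wald(pd.DataFrame({"x": x}), y).loc["x"]
            covered += row["or_low"] <= 1.0 <= row["or_high"]
        assert covered / reps == pytest.approx(0.95, abs=0.03)

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(14)
        beta_true = np.array([0.8, -0.5])
        hits = 0
        reps = 100
        for _ in range(reps):
            X = rng.standard_normal((300, 2))
            p = 1 / (1 + np.exp(-(X @ beta_true)))
            y = (rng.random(300) < p).astype(float)
            table = fit_logistic_wald(pd.DataFrame(X, columns=["a", "b"]), y)
            ok = all(
                abs(table.loc[t, "coef"] - b) <= 3 * table.loc[t, "se"]
                for t, b in zip(("a", "b"), beta_true)
            )
            hits += ok
        assert hits / reps >= 0.95


class TestDelongAuc:
    def brute_force_auc(self, scores, labels):
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        return wins / (len(pos) * len(neg))

    def test_perfect_separation_auc_one(self):
        auc, ci, _ = roc_auc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert ci[1] <= 1.0

    def test_null_scores_auc_near_half(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=2000)
        labels = (rng.random(2000) < 0.5).astype(float)
        auc, ci, _ = roc_auc_delong(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)
        assert ci[0] < 0.5 < ci[1]

    def test_auc_equals_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(16)
        for n in (20, 57, 200):
            scores = rng.integers(0, 10, size=n).astype(float)  # heavy ties
            labels = (rng.random(n) < 0.4).astype(float)
            if labels.sum() in (0, n):
                continue
            auc, _, _ = roc_auc_delong(scores, labels)
            assert auc == pytest.approx(self.brute_force_auc(scores, labels), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_delong([1.0, 2.0], [1, 1])

    def test_delong_ci_covers_true_auc(self):
        """Nominal coverage of the DeLong interval under a Gaussian shift."""
        from scipy import stats

        rng = np.random.default_rng(17)
        delta = 1.0
        true_auc = stats.norm.cdf(delta / np.sqrt(2))
        covered = 0
        reps = 300
        for _ in range(reps):
            pos = rng.normal(delta, size=50)
            neg = rng.normal(size=50)
            scores = np.concatenate([pos, neg])
            labels = np.concatenate([np.ones(50), np.zeros(50)])
            _, ci, _ = roc_auc_delong(scores, labels)
            covered += ci[0] <= true_auc <= ci[1]
        assert covered / reps == pytest.approx(0.95, abs=0.04)


class TestNomogram:
    @pytest.fixture
    def fitted(self):
        coef = {"a": 1.5, "b": -0.7, "c": 0.2}
        ranges = {"a": (0.0, 2.0), "b": (-1.0, 1.0), "c": (0.0, 5.0)}
        return make_nomogram(coef, intercept=-0.5, feature_ranges=ranges)

    def test_dominant_feature_spans_100_points(self, fitted):
        assert fitted.terms["points_max"].max() == pytest.approx(100.0)

    def test_zero_total_points_anchor_probability(self, fitted):
        # at every feature's reference end, eta = intercept + sum beta*x_ref
        eta = -0.5 + 1.5 * 0.0 + (-0.7) * 1.0 + 0.2 * 0.0
        assert fitted.probability(0.0) == pytest.approx(1 / (1 + np.exp(-eta)))

    def test_round_trip_probability_identity(self, fitted):
        rng = np.random.default_rng(18)
        coef = {"a": 1.5, "b": -0.7, "c": 0.2}
        for _ in range(100):
            x = {"a": rng.uniform(0, 2), "b": rng.uniform(-1, 1), "c": rng.uniform(0, 5)}
            eta = -0.5 + sum(coef[f] * x[f] for f in coef)
            direct = 1 / (1 + np.exp(-eta))
            via_points = fitted.probability(fitted.total_points(x))
            assert abs(via_points - direct) < 1e-9

    def test_points_are_nonnegative_and_monotone(self, fitted):
        grid = np.linspace(0, 2, 11)
        pts = [fitted.points({"a": v, "b": 0.0, "c": 0.0})["a"] for v in grid]
        assert pts[0] == pytest.approx(0.0)
        assert np.all(np.diff(pts) > 0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            make_nomogram({"a": 1.0}, 0.0, {"a": (2.0, 2.0)})


class TestPanelModel:
    def test_contrast_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            ContrastSpec("bad", ("H1",), ("H1", "0-CAD"))
        with pytest.raises(ValueError, match="nonempty"):
            ContrastSpec("bad", (), ("H1",))

    def test_stenosis_contrast_coding(self):
        table = simulate_panel_cohort(seed=19)
        model = StenosisPanelModel.from_feature_table(table, STENOSIS_CONTRAST)
        assert len(model.y) == 159
        assert model.y.sum() == 99  # 3 x 33 stenosis samples

    def test_fit_recovers_informative_features(self):
        table = simulate_panel_cohort(seed=20)
        model = StenosisPanelModel.from_feature_table(table, STENOSIS_CONTRAST)
        res = model.fit(seed=20)
        assert set(table.attrs["informative_features"]) <= set(res.selected_features)
        assert 0.8 <= res.auc <= 1.0
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]

    def test_summary_and_artifact(self):
        table = simulate_panel_cohort(seed=21)
        res = StenosisPanelModel.from_feature_table(table, STENOSIS_CONTRAST).fit(seed=21)
        text = res.summary()
        assert "AUC" in text and res.name in text
        artifact = res.to_dict()
        assert artifact["final_features"] == res.final_features
        import json

        json.dumps(artifact)  # serializable

    def test_nomogram_round_trip_on_fitted_model(self):
        table = simulate_panel_cohort(seed=22)
        model = StenosisPanelModel.from_feature_table(table, STENOSIS_CONTRAST)
        res = model.fit(seed=22)
        X = model.X[res.final_features]
        direct = res.predict(model.X)
        for i in range(0, len(X), 10):
            x = X.iloc[i].to_dict()
            assert abs(res.nomogram.probability(res.nomogram.total_points(x)) - direct[i]) < 1e-9

    def test_same_seed_reproduces_fit(self):
        table = simulate_panel_cohort(seed=23)
        model = StenosisPanelModel.from_feature_table(table, STENOSIS_CONTRAST)
        r1 = model.fit(seed=7)
        r2 = model.fit(seed=7)
        assert r1.lambda_min == r2.lambda_min
        assert r1.final_features == r2.final_features
        assert r1.auc == r2.auc
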