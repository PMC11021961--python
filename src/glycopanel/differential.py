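"""Pairwise differential screening of glycan features.

Every feature is tested between every unordered pair of study groups with
the two-sided Wilcoxon rank-sum (Mann–Whitney) test and gated on fold change:
a (feature, pair) result is *flagged* when the ratio of group means exceeds
1.1 or falls below 0.9 AND the rank-sum p-value is below 0.05.  A feature is
differential (``any_flagged``) when at least one pair passes the combined
gate.  No multiplicity correction is applied by default; Benjamini–Hochberg
adjustment of the p-values is available for reuse outside the original
screening design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import GROUPS
from .traits import feature_columns

__all__ = [
    "DifferentialReport",
    "wilcoxon_rank_sum",
    "fold_change",
    "significance_stars",
    "flag_differential",
]

logger = logging.getLogger(__name__)

#: Maximum combined sample size for the exact-enumeration p-value branch.
EXACT_MAX_N = 20


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) p-value.

    Uses exact enumeration of the U distribution when the combined sample
    size is at most ``EXACT_MAX_N`` and the data are tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.  Symmetric
    in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return 1.0  # all observations identical: no evidence by construction
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    result = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                use_continuity=True)
    return float(min(result.pvalue, 1.0))


def fold_change(x, y, center: str = "mean") -> float:
    """Fold change of group ``x`` relative to reference group ``y``.

    Ratio of group means by default (``center="median"`` available).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    agg = np.mean if center == "mean" else np.median
    ref = agg(y)
    if not ref > 0:
        raise ValueError(f"reference group {center} must be > 0, got {ref}")
    return float(agg(x) / ref)


def significance_stars(p: float) -> str:
    """Star annotation: ``*`` <0.05, ``**`` <0.01, ``***`` <0.001, ``****`` <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class DifferentialReport:
    """Pairwise screening results.

    Attributes
    ----------
    pairs : DataFrame
        One row per (feature, group pair): ``feature, group_a, group_b, n_a,
        n_b, fold_change, p_value, p_adjusted, stars, flagged``.
    any_flagged : Series (bool, indexed by feature)
        True where at least one pair passed the combined gate.
    """

    pairs: pd.DataFrame
    any_flagged: pd.Series

    @property
    def flagged_features(self) -> list[str]:
        return list(self.any_flagged.index[self.any_flagged])

    def to_long_format(self, table: pd.DataFrame) -> pd.DataFrame:
        """Violin-plot-ready long table of flagged features: sample, group, feature, value."""
        keep = self.flagged_features
        long = table.melt(
            id_vars=["group"], value_vars=keep, var_name="feature",
            value_name="value", ignore_index=False,
        )
        return long.reset_index()


def flag_differential(
    table: pd.DataFrame,
    groups: Sequence[str] | None = None,
    features: Sequence[str] | None = None,
    fc_low: float = 0.9,
    fc_high: float = 1.1,
    alpha: float = 0.05,
    center: str = "mean",
    adjust: str | None = None,
) -> DifferentialReport:
    """Screen every feature over every unordered group pair.

    Parameters
    ----------
    table : DataFrame
        Feature table with a ``group`` column (from ``build_feature_table``).
    groups : sequence of str, optional
        Ordered group labels to compare; defaults to the groups present, in
        first-appearance order.  For each pair the earlier-listed group is
        the reference: fold change = mean(later group) / mean(earlier group).
    fc_low, fc_high, alpha
        The combined gate: flagged ⇔ (fc > fc_high or fc < fc_low) and
        p < alpha, with strict inequalities on the fold-change boundaries.
    adjust : {None, "bh"}
        Optional Benjamini–Hochberg adjustment; the gate then uses the
        adjusted p-values.

    Groups with fewer than two samples are skipped with a warning.  Samples
    with a missing feature value are dropped pairwise for that feature.
    """
    if "group" not in table.columns:
        raise ValueError("feature table lacks a 'group' column")
    if groups is None:
        present_labels = set(table["group"])
        # canonical study-group order first, then any custom labels sorted,
        # so the report does not depend on sample-row order
        groups = [g for g in GROUPS if g in present_labels]
        groups += sorted(present_labels - set(GROUPS))
    if features is None:
        features = feature_columns(table)
    present = {g: table.index[table["group"] == g] for g in groups}
    usable = []
    for g in groups:
        if len(present[g]) < 2:
            logger.warning("group %s has <2 samples; its pairs are skipped", g)
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 samples")

    features = list(features)
    values_by_group = {
        g: table.loc[present[g], features].to_numpy(dtype=float) for g in usable
    }
    rows = []
    for ga, gb in itertools.combinations(usable, 2):
        a_all, b_all = values_by_group[ga], values_by_group[gb]
        clean = ~(np.isnan(a_all).any(axis=0) | np.isnan(b_all).any(axis=0))
        p_vec = np.full(len(features), np.nan)
        if a_all.shape[0] + b_all.shape[0] > EXACT_MAX_N and clean.any():
            # vectorized tie-corrected normal approximation across features
            res = stats.mannwhitneyu(
                a_all[:, clean], b_all[:, clean], alternative="two-sided",
                method="asymptotic", use_continuity=True, axis=0,
            )
            p_vec[clean] = np.minimum(np.nan_to_num(res.pvalue, nan=1.0), 1.0)
        for fi, feat in enumerate(features):
            a = a_all[:, fi]
            b = b_all[:, fi]
            if not clean[fi]:
                a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if a.size < 2 or b.size < 2:
                continue
            p = p_vec[fi] if not np.isnan(p_vec[fi]) else wilcoxon_rank_sum(a, b)
            try:
                fc = fold_change(b, a, center=center)
            except ValueError:
                fc = np.nan
            rows.append((feat, ga, gb, a.size, b.size, fc, p))
    pairs = pd.DataFrame(
        rows,
        columns=["feature", "group_a", "group_b", "n_a", "n_b", "fold_change", "p_value"],
    )
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        pairs["p_adjusted"] = multipletests(pairs["p_value"], method="fdr_bh")[1]
    elif adjust is None:
        pairs["p_adjusted"] = pairs["p_value"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    fc = pairs["fold_change"]
    pairs["stars"] = pairs["p_adjusted"].map(significance_stars)
    pairs["flagged"] = ((fc > fc_high) | (fc < fc_low)) & (pairs["p_adjusted"] < alpha)
    pairs.loc[fc.isna(), "flagged"] = False
    any_flagged = (
        pairs.groupby("feature", sort=False)["flagged"].any().reindex(features).fillna(False)
    )
    any_flagged.name = "any_flagged"
    return DifferentialReport(pairs=pairs, any_flagged=any_flagged)
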