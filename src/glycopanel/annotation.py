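"""Peak annotation against theoretical glycan m/z, replicate QC, normalization.

The annotation stage matches each filtered spectrum's peaks to the sodiated
theoretical m/z of a target composition list within a mass tolerance
(default ±0.2 Da, the centroiding peak width reused as matching window),
averages peak areas over technical replicates, applies the presence / CV
quality filters and finally normalizes each sample's quantified areas to the
total area of the selected glycans, yielding relative fractions that sum to
one per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compositions import GlycanComposition, sodiated_mz, _as_composition
from .spectra import PeakList, filter_peaks

__all__ = [
    "AnnotationResult",
    "CohortQuantification",
    "match_peaks",
    "quantify_replicates",
    "annotate_cohort",
    "qc_select_glycans",
    "normalize_total_area",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationResult:
    """Per-composition match record for one spectrum.

    ``table`` is indexed by composition string with columns ``theoretical_mz,
    matched, observed_mz, mass_error, area``; unmatched targets carry NaN in
    the observation columns.
    """

    table: pd.DataFrame

    @property
    def matched(self) -> pd.Series:
        return self.table["matched"]

    @property
    def area(self) -> pd.Series:
        return self.table["area"]


def _resolve_targets(targets: Iterable["GlycanComposition | str"]) -> tuple[list[str], np.ndarray]:
    comps = [_as_composition(t) for t in targets]
    names = [str(c) for c in comps]
    if len(set(names)) != len(names):
        raise ValueError("annotation targets must be distinct")
    theo = np.array([sodiated_mz(c) for c in comps])
    return names, theo


def match_peaks(
    pl: PeakList,
    targets: Sequence["GlycanComposition | str"],
    tolerance: float = 0.2,
) -> AnnotationResult:
    """Assign observed peaks to theoretical target m/z values.

    Each target takes the nearest peak within ``±tolerance`` of its sodiated
    m/z; each peak serves at most one target.  Conflicts are resolved
    globally by ascending |mass error| (nearest-target wins), ties broken
    toward the lower theoretical m/z; a target whose nearest peak is claimed
    falls back to its next-nearest free peak within tolerance.  Target pairs
    closer than twice the tolerance are flagged as ambiguous in the log.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    names, theo = _resolve_targets(targets)

    order = np.argsort(theo, kind="mergesort")
    gaps = np.diff(theo[order])
    for k in np.flatnonzero(gaps < 2 * tolerance):
        logger.warning(
            "ambiguous targets %s and %s are %.4f Da apart (< 2x tolerance %.3f)",
            names[order[k]], names[order[k + 1]], gaps[k], tolerance,
        )

    mz = pl.mz
    area = pl.area
    # All candidate (target, peak) pairs within tolerance, resolved greedily
    # by |error| then by lower theoretical m/z.
    candidates: list[tuple[float, float, int, int]] = []
    for ti, t_mz in enumerate(theo):
        lo = np.searchsorted(mz, t_mz - tolerance, side="left")
        hi = np.searchsorted(mz, t_mz + tolerance, side="right")
        for pi in range(lo, hi):
            candidates.append((abs(mz[pi] - t_mz), t_mz, ti, pi))
    candidates.sort()

    assigned_peak: dict[int, int] = {}
    used_peaks: set[int] = set()
    for _err, _tmz, ti, pi in candidates:
        if ti in assigned_peak or pi in used_peaks:
            continue
        assigned_peak[ti] = pi
        used_peaks.add(pi)

    obs_mz = np.full(len(names), np.nan)
    obs_area = np.full(len(names), np.nan)
    for ti, pi in assigned_peak.items():
        obs_mz[ti] = mz[pi]
        obs_area[ti] = area[pi]
    matched = ~np.isnan(obs_mz)
    table = pd.DataFrame(
        {
            "theoretical_mz": theo,
            "matched": matched,
            "observed_mz": obs_mz,
            "mass_error": obs_mz - theo,
            "area": obs_area,
        },
        index=pd.Index(names, name="composition"),
    )
    return AnnotationResult(table)


def quantify_replicates(
    annotations: Sequence[AnnotationResult],
    policy: str = "zero-fill",
) -> tuple[pd.Series, pd.Series]:
    """Average replicate peak areas per composition and compute replicate CV.

    Parameters
    ----------
    annotations : sequence of AnnotationResult
        One per technical replicate of the same sample (all over the same
        target list).
    policy : {"zero-fill", "skip"}
        ``zero-fill`` (default) treats an unmatched target as area 0, keeping
        the replicate count as denominator (absence = below detection);
        ``skip`` averages over matched replicates only.

    Returns
    -------
    (mean_area, cv) : two Series indexed by composition.  CV is the sample
    standard deviation (n−1) over the mean; it is NaN where the mean is 0 or
    fewer than two values contribute.
    """
    if len(annotations) == 0:
        raise ValueError("sample has zero replicates")
    if policy not in ("zero-fill", "skip"):
        raise ValueError(f"unknown missing-value policy {policy!r}")
    areas = pd.concat([a.area for a in annotations], axis=1)
    if policy == "zero-fill":
        values = areas.fillna(0.0)
    else:
        values = areas
    mean = values.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = values.std(axis=1, ddof=1)
        cv = sd / mean
    cv[(mean == 0) | values.count(axis=1).lt(2) | mean.isna()] = np.nan
    mean = mean.fillna(0.0)
    return mean, cv


@dataclass
class CohortQuantification:
    """Cohort-level annotation summary prior to QC selection.

    Attributes
    ----------
    mean_area : DataFrame, samples × compositions
        Replicate-mean matched peak areas.
    replicate_cv : DataFrame, samples × compositions
        Within-sample replicate coefficient of variation.
    presence : DataFrame, spectra × compositions (boolean)
        Whether each target matched in each individual spectrum; the row
        index is ``(sample_id, replicate index)``.
    """

    mean_area: pd.DataFrame
    replicate_cv: pd.DataFrame
    presence: pd.DataFrame

    @property
    def n_spectra(self) -> int:
        return len(self.presence)


def annotate_cohort(
    spectra: Mapping[str, Sequence[PeakList]],
    targets: Sequence["GlycanComposition | str"],
    tolerance: float = 0.2,
    snr_min: float = 4.0,
    mz_low: float = 1000.0,
    mz_high: float = 3000.0,
    policy: str = "zero-fill",
) -> CohortQuantification:
    """Filter, match and replicate-average every spectrum of a cohort.

    ``spectra`` maps sample id to its list of replicate peak lists (raw;
    the S/N and scan-range filters are applied here).
    """
    names, _ = _resolve_targets(targets)
    mean_rows, cv_rows, presence_rows, presence_index = [], [], [], []
    for sample_id, replicates in spectra.items():
        anns = []
        for ri, pl in enumerate(replicates):
            filtered = filter_peaks(pl, snr_min=snr_min, mz_low=mz_low, mz_high=mz_high)
            ann = match_peaks(filtered, targets, tolerance=tolerance)
            anns.append(ann)
            presence_rows.append(ann.matched.to_numpy())
            presence_index.append((sample_id, ri))
        mean, cv = quantify_replicates(anns, policy=policy)
        mean_rows.append(mean)
        cv_rows.append(cv)
    sample_ids = list(spectra.keys())
    mean_area = pd.DataFrame(mean_rows, index=pd.Index(sample_ids, name="sample_id"))
    replicate_cv = pd.DataFrame(cv_rows, index=pd.Index(sample_ids, name="sample_id"))
    presence = pd.DataFrame(
        np.array(presence_rows, dtype=bool),
        index=pd.MultiIndex.from_tuples(presence_index, names=["sample_id", "replicate"]),
        columns=names,
    )
    return CohortQuantification(mean_area[names], replicate_cv[names], presence)


def qc_select_glycans(
    quant: CohortQuantification,
    presence_min: float = 0.5,
    cv_max: float = 0.2,
) -> tuple[list[str], pd.DataFrame]:
    """Select reliably quantified compositions.

    A composition is kept when it is detected in strictly more than
    ``presence_min`` of all individual spectra AND its median across-sample
    replicate CV is strictly below ``cv_max``.

    Returns the kept composition list (registry order) and a QC report with
    per-composition presence counts/fractions, median CV and the kept flag.
    """
    if not (0 < presence_min < 1):
        raise ValueError("presence_min must lie in (0, 1)")
    if cv_max <= 0:
        raise ValueError("cv_max must be > 0")
    n_spectra = quant.n_spectra
    presence_count = quant.presence.sum(axis=0)
    presence_fraction = presence_count / n_spectra
    median_cv = quant.replicate_cv.median(axis=0, skipna=True)
    kept = (presence_fraction > presence_min) & (median_cv < cv_max)
    report = pd.DataFrame(
        {
            "presence_count": presence_count.astype(int),
            "presence_fraction": presence_fraction,
            "median_cv": median_cv,
            "kept": kept.fillna(False),
        }
    )
    report.index.name = "composition"
    selected = [c for c in quant.mean_area.columns if bool(report.loc[c, "kept"])]
    logger.info("QC kept %d/%d compositions over %d spectra", len(selected), len(report), n_spectra)
    return selected, report


def normalize_total_area(mean_area: pd.DataFrame, selected: Sequence[str] | None = None) -> pd.DataFrame:
    """Convert mean areas to total-area-normalized fractions.

    Each sample's area over the selected compositions is divided by the
    sample's total over those compositions, so every row sums to one.
    """
    if selected is not None:
        if len(selected) == 0:
            raise ValueError("no compositions selected for normalization")
        mean_area = mean_area[list(selected)]
    if mean_area.shape[1] == 0:
        raise ValueError("no compositions selected for normalization")
    totals = mean_area.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(
            f"sample(s) with all-zero quantified areas: {list(zero.index)}"
        )
    return mean_area.div(totals, axis=0)
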