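"""Peak-list and cohort-manifest I/O plus acquisition-level peak filtering.

A *peak list* is one centroided MALDI-TOF spectrum exported as a table with
one row per peak: m/z, peak area, peak intensity and signal-to-noise ratio
(S/N).  The native dialect is tab-separated with header ``mz  area  intensity
snr``; a permissive CSV reader with column-name mapping accommodates other
export formats.  Optional columns (intensity, snr, resolution) may be absent
and are carried as NaN ("unknown").

The *cohort manifest* is a CSV with one row per serum sample: ``sample_id``,
``group`` (one of H1, 0-CAD, 1-CAD, 2-CAD, 3-CAD — healthy controls plus four
angiography-graded stenosis classes), the technical-replicate spectrum paths
``rep1..repN`` and optional clinical covariates (age, sex, LDL, HDL, TC, TG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CLINICAL_COLUMNS",
    "PeakList",
    "CohortManifest",
    "read_peak_list",
    "write_peak_list",
    "filter_peaks",
    "read_cohort_manifest",
    "write_cohort_manifest",
]

logger = logging.getLogger(__name__)

#: Fixed group vocabulary: healthy controls and the four stenosis grades.
GROUPS: tuple[str, ...] = ("H1", "0-CAD", "1-CAD", "2-CAD", "3-CAD")

CLINICAL_COLUMNS: tuple[str, ...] = ("age", "sex", "ldl", "hdl", "tc", "tg")

_PEAK_COLUMNS = ("mz", "area", "intensity", "snr")
_MANDATORY_PEAK_COLUMNS = ("mz", "area")

# Common export-header spellings mapped onto the native column names.
_DEFAULT_COLUMN_MAP = {
    "m/z": "mz",
    "mass": "mz",
    "peak area": "area",
    "peak intensity": "intensity",
    "intens.": "intensity",
    "s/n": "snr",
    "sn": "snr",
    "resolution": "resolution",
    "res.": "resolution",
}


@dataclass(frozen=True)
class PeakList:
    """One spectrum's centroided peaks, sorted by m/z ascending.

    Wraps a DataFrame with columns ``mz, area, intensity, snr`` (+ optional
    ``resolution``); unknown optional values are NaN.
    """

    peaks: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        df = self.peaks
        missing = [c for c in _MANDATORY_PEAK_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"peak table missing mandatory column(s): {missing}")
        df = df.copy()
        for col in _PEAK_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col])
        if (df["area"].fillna(0) < 0).any() or (df["intensity"].fillna(0) < 0).any():
            raise ValueError("peak area/intensity must be non-negative")
        df = df.sort_values("mz", kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "peaks", df)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return self.peaks["mz"].to_numpy()

    @property
    def area(self) -> np.ndarray:
        return self.peaks["area"].to_numpy()

    @property
    def snr(self) -> np.ndarray:
        return self.peaks["snr"].to_numpy()

    @classmethod
    def from_arrays(
        cls,
        mz: Sequence[float],
        area: Sequence[float],
        intensity: Sequence[float] | None = None,
        snr: Sequence[float] | None = None,
        source: str = "",
    ) -> "PeakList":
        n = len(mz)
        df = pd.DataFrame(
            {
                "mz": np.asarray(mz, dtype=float),
                "area": np.asarray(area, dtype=float),
                "intensity": np.full(n, np.nan) if intensity is None else np.asarray(intensity, dtype=float),
                "snr": np.full(n, np.nan) if snr is None else np.asarray(snr, dtype=float),
            }
        )
        return cls(df, source=source)


def read_peak_list(path, dialect: str = "native", column_map: Mapping[str, str] | None = None) -> PeakList:
    """Read one exported peak list.

    Parameters
    ----------
    path : path-like
        Peak-list file.
    dialect : {"native", "csv"}
        ``native`` is the package's tab-separated format; ``csv`` is a
        permissive comma-separated reader with header-name mapping.
    column_map : mapping, optional
        Extra ``{export header -> native name}`` entries for odd exports.
    """
    path = Path(path)
    sep = "\t" if dialect == "native" else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"unreadable peak list {path}: {exc}") from exc
    mapping = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        mapping.update(column_map)
    df.columns = [mapping.get(str(c).strip().lower(), str(c).strip().lower()) for c in df.columns]
    missing = [c for c in _MANDATORY_PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"peak list {path} missing mandatory column(s): {missing}")
    for col in df.columns:
        if col in _PEAK_COLUMNS or col == "resolution":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any() and col in _MANDATORY_PEAK_COLUMNS:
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"peak list {path}: non-numeric {col!r} value {df[col].iloc[row]!r} at row {row}"
                )
            df[col] = coerced
    return PeakList(df, source=str(path))


def write_peak_list(pl: PeakList, path) -> None:
    """Write a peak list in the native tab-separated dialect."""
    cols = [c for c in (*_PEAK_COLUMNS, "resolution") if c in pl.peaks.columns]
    pl.peaks.to_csv(path, sep="\t", index=False, columns=cols)


def filter_peaks(
    pl: PeakList,
    snr_min: float = 4.0,
    mz_low: float = 1000.0,
    mz_high: float = 3000.0,
    strict_snr: bool = False,
) -> PeakList:
    """Apply the acquisition-level peak filters.

    Retains peaks with ``snr >= snr_min`` (closed threshold) and m/z inside
    ``[mz_low, mz_high]``.  Peaks with unknown S/N are retained by default
    (permissive); ``strict_snr=True`` drops them.  Order is preserved, and the
    operation is idempotent.
    """
    if not (np.isfinite(snr_min) and np.isfinite(mz_low) and np.isfinite(mz_high)):
        raise ValueError("filter thresholds must be finite")
    if snr_min < 0:
        raise ValueError("snr_min must be >= 0")
    df = pl.peaks
    snr = df["snr"]
    snr_ok = snr >= snr_min
    if not strict_snr:
        snr_ok |= snr.isna()
    keep = snr_ok & df["mz"].between(mz_low, mz_high)
    return PeakList(df.loc[keep].reset_index(drop=True), source=pl.source)


@dataclass
class CohortManifest:
    """Validated cohort design table.

    ``samples`` has one row per sample with columns ``sample_id``, ``group``,
    replicate path columns ``rep1..repN`` and any clinical covariates present.
    """

    samples: pd.DataFrame
    replicate_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        df = self.samples.reset_index(drop=True)
        if "sample_id" not in df.columns or "group" not in df.columns:
            raise ValueError("manifest requires sample_id and group columns")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dup))}")
        unknown = sorted(set(df["group"]) - set(GROUPS))
        if unknown:
            raise ValueError(f"unknown group label(s) {unknown}; expected one of {GROUPS}")
        if not self.replicate_columns:
            self.replicate_columns = tuple(
                c for c in df.columns if c.startswith("rep") and c[3:].isdigit()
            )
        self.samples = df

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def group_of(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]

    def group_counts(self) -> dict[str, int]:
        counts = self.samples["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUPS}

    def replicate_paths(self, sample_id: str) -> list[str]:
        row = self.samples.set_index("sample_id").loc[sample_id]
        return [str(row[c]) for c in self.replicate_columns if pd.notna(row.get(c))]

    def clinical(self) -> pd.DataFrame:
        cols = [c for c in CLINICAL_COLUMNS if c in self.samples.columns]
        return self.samples.set_index("sample_id")[cols]


def read_cohort_manifest(path, check_paths: bool = True) -> CohortManifest:
    """Read and validate a cohort manifest CSV.

    Raises on duplicate sample ids, unknown group labels and (when
    ``check_paths``) dangling replicate paths; per-group sample counts are
    reported in the log.
    """
    path = Path(path)
    df = pd.read_csv(path)
    manifest = CohortManifest(df)
    if check_paths:
        base = path.parent
        for sid in manifest.sample_ids:
            for rep in manifest.replicate_paths(sid):
                rep_path = Path(rep)
                if not rep_path.is_absolute():
                    rep_path = base / rep_path
                if not rep_path.exists():
                    raise ValueError(f"sample {sid}: dangling replicate path {rep}")
    logger.info("manifest %s: %d samples, per-group counts %s", path, len(manifest), manifest.group_counts())
    return manifest


def write_cohort_manifest(manifest: CohortManifest, path) -> None:
    manifest.samples.to_csv(path, index=False)
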