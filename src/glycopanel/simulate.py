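"""Synthetic cohorts with the statistical structure the pipeline assumes.

Three generators cover the pipeline's stages:

* :func:`generate_cohort` renders a full spectral cohort — per-sample true
  glycan abundances (log-normal, spread over about two orders of magnitude),
  multiplicative group effects, technical replicates with multiplicative
  area noise and Gaussian m/z jitter, decoy peaks away from every target,
  and group-independent clinical covariates — exercising annotation, QC and
  normalization end to end.
* :func:`simulate_feature_table` draws a feature table directly (log-normal
  features with multiplicative group shifts on named features), the natural
  fixture for the differential-screening stage where planted effects must
  stay confined to the named features.
* :func:`simulate_panel_cohort` draws a binary-outcome cohort whose optimal
  discriminant has a *known* construction AUC (Gaussian location-shift
  model: AUC = Φ(Δ/√2) with Δ the Mahalanobis separation), for
  parameter-recovery tests of the panel-modelling stage.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compositions import GlycanComposition, default_registry, sodiated_mz
from .spectra import GROUPS, CohortManifest, PeakList, write_cohort_manifest, write_peak_list

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "render_spectrum",
    "plant_effects",
    "expected_fraction_fold_changes",
    "DIFFERENTIAL_FEATURES",
    "default_differential_effects",
    "simulate_feature_table",
    "simulate_panel_cohort",
]

#: Default group sizes: 27 healthy controls + 132 patients over four grades.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "H1": 27, "0-CAD": 33, "1-CAD": 33, "2-CAD": 33, "3-CAD": 33,
}

#: The 18 feature labels used by default for differential-recovery cohorts.
DIFFERENTIAL_FEATURES: tuple[str, ...] = (
    "IGP9", "IGP20", "IGP26", "IGP28", "IGP29", "IGP30", "IGP33", "IGP41",
    "IGP43", "IGP50", "IGP52", "IGP62", "IGP64", "IGP66", "IGP67", "IGP70",
    "IGP73", "IGP74",
)


@dataclass
class SimulationConfig:
    """Configuration of the spectral cohort generator.

    Defaults emulate the study design: 159 samples (27 + 4×33) with three
    technical replicates each, 27 target compositions in m/z 1000–3000,
    log-normal abundances, 5% replicate CV, 0.03 Da m/z jitter, and 60 decoy
    peaks per spectrum kept at least 0.5 Da from every target.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    replicates: int = 3
    compositions: list[str] | None = None  # None = bundled 27-entry registry
    base_log_area: tuple[float, float] = (np.log(2e3), np.log(2e5))
    biological_sigma: float = 0.25  # between-sample log-scale SD
    replicate_cv: float = 0.05  # multiplicative technical noise
    mz_jitter_sd: float = 0.03  # Da
    n_decoys: int = 60
    decoy_exclusion: float = 0.5  # Da around every target
    missing_rate: float = 0.0  # per-replicate true-peak dropout
    mz_range: tuple[float, float] = (1000.0, 3000.0)
    true_snr_range: tuple[float, float] = (10.0, 50.0)
    decoy_snr_range: tuple[float, float] = (1.0, 8.0)
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    clinical_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 samples")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
        for name in ("biological_sigma", "replicate_cv", "mz_jitter_sd", "missing_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for comp, shifts in self.effects.items():
            for group, mult in shifts.items():
                if mult <= 0:
                    raise ValueError(f"effect multiplier for ({comp}, {group}) must be > 0")

    def composition_names(self) -> list[str]:
        from .compositions import parse_composition

        if self.compositions is None:
            return [str(c) for c in default_registry()]
        return [str(parse_composition(c)) for c in self.compositions]


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort: manifest, spectra and ground truth."""

    manifest: CohortManifest
    spectra: dict[str, list[PeakList]]
    truth: dict

    def write(self, out_dir) -> None:
        """Persist as manifest CSV + per-spectrum TSV files + truth JSON."""
        out_dir = Path(out_dir)
        spectra_dir = out_dir / "spectra"
        spectra_dir.mkdir(parents=True, exist_ok=True)
        manifest = self.manifest.samples.copy()
        for sid, replicates in self.spectra.items():
            for ri, pl in enumerate(replicates):
                rel = f"spectra/{sid}_rep{ri + 1}.tsv"
                write_peak_list(pl, out_dir / rel)
                manifest.loc[manifest["sample_id"] == sid, f"rep{ri + 1}"] = rel
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        with open(out_dir / "ground_truth.json", "w", encoding="utf-8") as handle:
            json.dump(self.truth, handle, indent=1)


def _decoy_mz(rng: np.random.Generator, n: int, mz_range: tuple[float, float],
              target_mz: np.ndarray, exclusion: float) -> np.ndarray:
    """Uniform decoy m/z avoiding ±exclusion Da around every target."""
    lo, hi = mz_range
    excluded = 0.0
    for t in target_mz:
        excluded += min(t + exclusion, hi) - max(t - exclusion, lo)
    if excluded >= (hi - lo):
        raise ValueError("decoy exclusion zones cover the entire scan range")
    out = np.empty(0)
    while out.size < n:
        draw = rng.uniform(lo, hi, size=2 * (n - out.size) + 8)
        dist = np.min(np.abs(draw[:, None] - target_mz[None, :]), axis=1)
        out = np.concatenate([out, draw[dist > exclusion]])
    return out[:n]


def render_spectrum(
    true_areas: Mapping[str, float],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> PeakList:
    """Render one replicate spectrum from a sample's true abundances.

    One peak per detected target at its sodiated m/z plus Gaussian jitter,
    with area multiplied by log-normal technical noise of the configured CV;
    true peaks draw S/N above the acquisition threshold, decoys straddle it.
    """
    names = list(true_areas)
    theo = np.array([sodiated_mz(c) for c in names])
    areas = np.array([true_areas[c] for c in names], dtype=float)
    if (areas < 0).any():
        raise ValueError("true areas must be >= 0")
    detected = rng.random(len(names)) >= cfg.missing_rate
    detected &= areas > 0
    sigma = np.sqrt(np.log1p(cfg.replicate_cv**2))
    noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=len(names))
    mz = theo + rng.normal(0.0, cfg.mz_jitter_sd, size=len(names))
    snr = rng.uniform(*cfg.true_snr_range, size=len(names))
    obs_mz = mz[detected]
    obs_area = (areas * noise)[detected]
    obs_snr = snr[detected]

    n_dec = cfg.n_decoys
    dec_mz = _decoy_mz(rng, n_dec, cfg.mz_range, theo, cfg.decoy_exclusion)
    dec_area = rng.lognormal(mean=np.log(500.0), sigma=1.0, size=n_dec)
    dec_snr = rng.uniform(*cfg.decoy_snr_range, size=n_dec)

    all_mz = np.concatenate([obs_mz, dec_mz])
    all_area = np.concatenate([obs_area, dec_area])
    all_snr = np.concatenate([obs_snr, dec_snr])
    return PeakList.from_arrays(all_mz, all_area, intensity=all_area, snr=all_snr)


def plant_effects(
    compositions: Sequence[str],
    shifts: Mapping[str, Mapping[str, float]],
) -> dict[str, dict[str, float]]:
    """Validate and normalize an effect map ``{composition: {group: mult}}``.

    Multiplicative shifts act on the raw-abundance scale before
    normalization; see :func:`expected_fraction_fold_changes` for the induced
    effect on normalized fractions.
    """
    known = set(compositions)
    out: dict[str, dict[str, float]] = {}
    for comp, by_group in shifts.items():
        if comp not in known:
            raise ValueError(f"unknown composition {comp!r} in effect map")
        for group, mult in by_group.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r} in effect map")
            if mult <= 0:
                raise ValueError(f"multiplier for ({comp}, {group}) must be > 0")
            out.setdefault(comp, {})[group] = float(mult)
    return out


def _expected_abundances(cfg: SimulationConfig, names: Sequence[str]) -> np.ndarray:
    lo, hi = cfg.base_log_area
    k = len(names)
    mu = np.linspace(lo, hi, k) if k > 1 else np.array([(lo + hi) / 2])
    return np.exp(mu + cfg.biological_sigma**2 / 2)


def expected_fraction_fold_changes(
    cfg: SimulationConfig,
    group: str,
    reference: str = "H1",
) -> pd.Series:
    """Closed-form expected fold change of every normalized fraction.

    With expected raw abundances ``a_i`` and multiplicative group effects
    ``m_i``, a composition's expected normalized fraction is
    ``m_i a_i / Σ_j m_j a_j``; the returned fold change is that share in
    ``group`` divided by the share in ``reference``.  This records the
    closure effect: planting a shift on one composition moves all other
    fractions in the opposite direction.
    """
    names = cfg.composition_names()
    base = _expected_abundances(cfg, names)

    def shares(g: str) -> np.ndarray:
        mult = np.array([cfg.effects.get(c, {}).get(g, 1.0) for c in names])
        raw = base * mult
        return raw / raw.sum()

    fc = shares(group) / shares(reference)
    return pd.Series(fc, index=pd.Index(names, name="composition"), name=f"{group}/{reference}")


_CLINICAL_MODEL = {
    "age": (65.0, 8.0), "ldl": (2.8, 0.8), "hdl": (1.2, 0.3),
    "tc": (4.5, 1.0), "tg": (1.6, 0.7),
}


def generate_cohort(cfg: SimulationConfig, out_dir=None) -> SyntheticCohort:
    """Generate a full spectral cohort; optionally persist it to ``out_dir``.

    Per sample, true abundances are drawn once (log-normal around the
    configured per-composition baselines, times any group effect) and each
    replicate spectrum is rendered independently.  The ground-truth record
    (true abundances, expected fractions, effect map) suffices to compute
    every expected value used by recovery tests.
    """
    rng = np.random.default_rng(cfg.seed)
    names = cfg.composition_names()
    effects = plant_effects(names, cfg.effects)
    lo, hi = cfg.base_log_area
    mu = np.linspace(lo, hi, len(names)) if len(names) > 1 else np.array([(lo + hi) / 2])

    rows = []
    spectra: dict[str, list[PeakList]] = {}
    true_areas_record: dict[str, dict[str, float]] = {}
    counter = 0
    for group in GROUPS:
        n = cfg.group_sizes.get(group, 0)
        mult = np.array([effects.get(c, {}).get(group, 1.0) for c in names])
        for _ in range(n):
            counter += 1
            sid = f"S{counter:03d}"
            true = np.exp(mu + cfg.biological_sigma * rng.standard_normal(len(names))) * mult
            true_areas_record[sid] = {c: float(a) for c, a in zip(names, true)}
            spectra[sid] = [
                render_spectrum(dict(zip(names, true)), cfg, rng)
                for _ in range(cfg.replicates)
            ]
            clinical = {}
            for col, (m, s) in _CLINICAL_MODEL.items():
                shift = cfg.clinical_effects.get(col, {}).get(group, 0.0)
                clinical[col] = float(rng.normal(m + shift, s))
            clinical["sex"] = int(rng.random() < 0.5)
            rows.append({"sample_id": sid, "group": group, **clinical})
    samples = pd.DataFrame(rows)
    for ri in range(cfg.replicates):
        samples[f"rep{ri + 1}"] = ""  # paths filled on write()
    manifest = CohortManifest(samples)
    truth = {
        "config": {k: v for k, v in asdict(cfg).items() if k != "compositions"},
        "compositions": names,
        "effects": effects,
        "true_areas": true_areas_record,
        "expected_fraction_fold_changes": {
            g: expected_fraction_fold_changes(cfg, g).to_dict()
            for g in GROUPS
            if any(g in by_group for by_group in effects.values())
        },
    }
    cohort = SyntheticCohort(manifest=manifest, spectra=spectra, truth=truth)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


# ---------------------------------------------------------------------------
# Feature-level simulators
# ---------------------------------------------------------------------------

def default_differential_effects(
    features: Sequence[str] = DIFFERENTIAL_FEATURES,
    fold: float = 1.5,
) -> dict[str, dict[str, float]]:
    """Assign each named feature a ≥``fold`` shift in one stenosis group.

    Features cycle over the four non-control groups, alternating up- and
    down-shifts, so every group carries planted signal.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    shifted_groups = [g for g in GROUPS if g != "H1"]
    out: dict[str, dict[str, float]] = {}
    for k, feat in enumerate(features):
        group = shifted_groups[k % len(shifted_groups)]
        mult = fold if k % 2 == 0 else 1.0 / fold
        out[feat] = {group: mult}
    return out


def simulate_feature_table(
    n_per_group: int | Mapping[str, int] = 25,
    n_features: int = 74,
    effects: Mapping[str, Mapping[str, float]] | None = None,
    sigma_log: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a feature table directly: log-normal features, planted shifts.

    Features are labelled IGP1..IGPk; ``effects`` maps feature → group →
    multiplicative shift (default: no effects, a null cohort).  ``sigma_log``
    is the between-sample log-scale SD shared by all features.  The returned
    table carries a ``group`` column and ``attrs["planted_features"]``.
    """
    rng = np.random.default_rng(seed)
    features = [f"IGP{i + 1}" for i in range(n_features)]
    effects = dict(effects or {})
    unknown = set(effects) - set(features)
    if unknown:
        raise ValueError(f"unknown feature(s) in effect map: {sorted(unknown)}")
    if isinstance(n_per_group, int):
        sizes = {g: n_per_group for g in GROUPS}
    else:
        sizes = dict(n_per_group)
    base_mu = np.linspace(np.log(0.005), np.log(0.2), n_features)
    rows, groups, index = [], [], []
    counter = 0
    for group in GROUPS:
        n = sizes.get(group, 0)
        mult = np.array([effects.get(f, {}).get(group, 1.0) for f in features])
        values = np.exp(base_mu + sigma_log * rng.standard_normal((n, n_features))) * mult
        rows.append(values)
        groups += [group] * n
        index += [f"S{counter + i + 1:03d}" for i in range(n)]
        counter += n
    table = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="sample_id"), columns=features)
    table.attrs["feature_columns"] = features
    table.attrs["planted_features"] = sorted(effects, key=features.index)
    table["group"] = groups
    return table


def simulate_panel_cohort(
    group_sizes: Mapping[str, int] | None = None,
    construction_auc: float = 0.9,
    informative: Sequence[str] = ("IGP33", "IGP66", "IGP70"),
    features: Sequence[str] = DIFFERENTIAL_FEATURES,
    clinical: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary-outcome cohort with a known-by-construction discrimination AUC.

    The outcome is stenosis (groups 1/2/3-CAD) vs no stenosis (H1, 0-CAD).
    Each informative feature is shifted by δ in the stenosis samples with
    δ chosen so the optimal discriminant's AUC equals ``construction_auc``
    exactly: for k independent unit-variance features, AUC = Φ(√(kδ²)/√2).
    All other features, and all clinical covariates, are independent of the
    outcome (null).  ``attrs`` records the construction AUC and informative
    set.
    """
    if not 0.5 < construction_auc < 1:
        raise ValueError("construction_auc must lie in (0.5, 1)")
    unknown = set(informative) - set(features)
    if unknown:
        raise ValueError(f"informative features not in candidate set: {sorted(unknown)}")
    sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    rng = np.random.default_rng(seed)
    k = len(informative)
    delta = np.sqrt(2.0) * stats.norm.ppf(construction_auc) / np.sqrt(k)
    rows, groups = [], []
    for group in GROUPS:
        n = sizes.get(group, 0)
        stenosed = group in ("1-CAD", "2-CAD", "3-CAD")
        x = rng.standard_normal((n, len(features)))
        if stenosed:
            for feat in informative:
                x[:, list(features).index(feat)] += delta
        rows.append(x)
        groups += [group] * n
    table = pd.DataFrame(
        np.vstack(rows),
        index=pd.Index([f"S{i + 1:03d}" for i in range(len(groups))], name="sample_id"),
        columns=list(features),
    )
    table.attrs["feature_columns"] = list(features)
    table.attrs["construction_auc"] = construction_auc
    table.attrs["informative_features"] = list(informative)
    if clinical:
        for col, (m, s) in _CLINICAL_MODEL.items():
            table[col] = rng.normal(m, s, size=len(table))
        table["sex"] = (rng.random(len(table)) < 0.5).astype(int)
    table["group"] = groups
    return table
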