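"""End-to-end pipeline orchestration: simulate → annotate → traits → diff → panel.

``run_pipeline`` executes the stages in order from a validated
:class:`RunConfig`, persists every intermediate artifact under the output
directory and returns a machine-readable run report (per-stage counts,
selected glycans, flagged features, per-contrast AUCs).  A run is a pure
function of (inputs, config, seed): the same config and seed reproduce the
same report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, differential, panels, simulate, traits
from .compositions import default_registry, load_registry
from .spectra import read_cohort_manifest, read_peak_list

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated parameters of one pipeline run."""

    out_dir: str = "glycopanel_run"
    seed: int = 0
    # input: either an existing manifest, or simulate a cohort
    manifest: str | None = None
    simulate: bool = True
    registry: str | None = None  # composition list file; None = bundled
    trait_catalog: str | None = None  # YAML; None = bundled 47-trait catalog
    # stage parameters
    snr_min: float = 4.0
    mz_low: float = 1000.0
    mz_high: float = 3000.0
    tolerance: float = 0.2
    presence_min: float = 0.5
    cv_max: float = 0.2
    fc_low: float = 0.9
    fc_high: float = 1.1
    alpha: float = 0.05
    folds: int = 10
    with_clinical: bool = True
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if not (0 < self.presence_min < 1):
            raise ValueError("presence_min must lie in (0, 1)")
        if self.cv_max <= 0 or self.tolerance <= 0:
            raise ValueError("cv_max and tolerance must be > 0")
        if self.snr_min < 0:
            raise ValueError("snr_min must be >= 0")
        if not (0 < self.fc_low <= 1 <= self.fc_high):
            raise ValueError("fold-change gates must bracket 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.mz_low >= self.mz_high:
            raise ValueError("empty m/z range")
        if not self.simulate and self.manifest is None:
            raise ValueError("either enable the simulate stage or provide a manifest")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)


def _load_spectra(manifest, base: Path):
    spectra = {}
    for sid in manifest.sample_ids:
        reps = []
        for rel in manifest.replicate_paths(sid):
            p = Path(rel)
            reps.append(read_peak_list(p if p.is_absolute() else base / p))
        spectra[sid] = reps
    return spectra


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages and return the report dict (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    # --- stage: input (simulate or load) -----------------------------------
    if cfg.simulate:
        sim_cfg = simulate.SimulationConfig(**{"seed": cfg.seed, **cfg.sim})
        cohort = simulate.generate_cohort(sim_cfg, out_dir=out / "cohort")
        manifest, spectra = cohort.manifest, cohort.spectra
    else:
        manifest = read_cohort_manifest(cfg.manifest)
        spectra = _load_spectra(manifest, Path(cfg.manifest).parent)
    n_spectra = sum(len(v) for v in spectra.values())
    report["stages"]["input"] = {
        "samples": len(manifest),
        "group_counts": manifest.group_counts(),
        "spectra": n_spectra,
    }

    # --- stage: annotation + QC + normalization ----------------------------
    registry = load_registry(cfg.registry) if cfg.registry else default_registry()
    quant = annotation.annotate_cohort(
        spectra, registry, tolerance=cfg.tolerance, snr_min=cfg.snr_min,
        mz_low=cfg.mz_low, mz_high=cfg.mz_high,
    )
    selected, qc_report = annotation.qc_select_glycans(
        quant, presence_min=cfg.presence_min, cv_max=cfg.cv_max,
    )
    qc_report.to_csv(out / "qc_report.csv")
    fractions = annotation.normalize_total_area(quant.mean_area, selected)
    fractions.to_csv(out / "glycan_fractions.csv")
    report["stages"]["annotation"] = {
        "targets": len(registry),
        "glycans_selected": len(selected),
        "selected": selected,
    }

    # --- stage: derived traits ---------------------------------------------
    catalog = traits.load_trait_catalog(cfg.trait_catalog) if cfg.trait_catalog else traits.default_trait_catalog()
    table = traits.build_feature_table(fractions, catalog, manifest)
    table.to_csv(out / "feature_table.csv")
    n_features = len(traits.feature_columns(table))
    report["stages"]["traits"] = {
        "derived_traits": len(catalog),
        "feature_columns": n_features,
    }

    # --- stage: differential screening -------------------------------------
    diff = differential.flag_differential(
        table, fc_low=cfg.fc_low, fc_high=cfg.fc_high, alpha=cfg.alpha,
    )
    diff.pairs.to_csv(out / "differential_report.csv", index=False)
    flagged = diff.flagged_features
    report["stages"]["differential"] = {
        "pairs_tested": len(diff.pairs),
        "features_flagged": len(flagged),
        "flagged": flagged,
    }

    # --- stage: panel models ------------------------------------------------
    candidates = flagged if flagged else None
    contrasts = panels.default_contrasts(with_clinical=cfg.with_clinical)
    results = panels.run_panel_analysis(
        table, contrasts, candidate_features=candidates,
        folds=cfg.folds, seed=cfg.seed,
    )
    panel_summary = {}
    for name, res in results.items():
        artifact = res.to_dict()
        with open(out / f"panel_{name.replace('+', '_')}.json", "w", encoding="utf-8") as handle:
            json.dump(artifact, handle, indent=1)
        res.roc_points.to_csv(out / f"roc_{name.replace('+', '_')}.csv", index=False)
        panel_summary[name] = {
            "final_features": res.final_features,
            "auc": round(res.auc, 6),
            "auc_ci": [round(x, 6) for x in res.auc_ci],
        }
    report["stages"]["panels"] = {
        "models_fitted": len(results),
        "models": panel_summary,
    }

    with open(out / "report.json", "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=1, sort_keys=True)
    return report
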