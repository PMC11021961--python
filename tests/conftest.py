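import numpy as np
import pytest

from glycopanel.annotation import annotate_cohort, normalize_total_area, qc_select_glycans
from glycopanel.compositions import default_registry
from glycopanel.simulate import SimulationConfig, generate_cohort

# Elemental monoisotopic masses for the independent mass oracle.
ELEMENT_MASSES = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
    "e": 0.00054857990907,
}

# Residue elemental formulas (dehydrated residues) + water for the free glycan.
RESIDUE_FORMULAS = {
    "hex": {"C": 6, "H": 10, "O": 5},
    "hexnac": {"C": 8, "H": 13, "N": 1, "O": 5},
    "dhex": {"C": 6, "H": 10, "O": 4},
    "neuac": {"C": 11, "H": 17, "N": 1, "O": 8},
}


def elemental_sodiated_mz(comp) -> float:
    """Independent oracle: [M+Na]+ m/z from summed atomic masses."""
    atoms: dict[str, float] = {"H": 2, "O": 1}  # water
    for residue, count in (
        ("hex", comp.hex), ("hexnac", comp.hexnac),
        ("dhex", comp.dhex), ("neuac", comp.neuac),
    ):
        for el, n in RESIDUE_FORMULAS[residue].items():
            atoms[el] = atoms.get(el, 0) + n * count
    mass = sum(ELEMENT_MASSES[el] * n for el, n in atoms.items())
    return mass + ELEMENT_MASSES["Na"] - ELEMENT_MASSES["e"]


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (159 samples x 3 replicates)."""
    return generate_cohort(SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def default_fractions(default_cohort, registry):
    """QC-selected, total-area-normalized fractions of the default cohort."""
    quant = annotate_cohort(default_cohort.spectra, registry)
    selected, report = qc_select_glycans(quant)
    fractions = normalize_total_area(quant.mean_area, selected)
    return fractions, selected, report
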