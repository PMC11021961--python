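"""N-glycan composition algebra.

Serum N-glycans measured by MALDI-TOF MS are reported as monosaccharide
*compositions* — counts of hexose (Hex: mannose/galactose), N-acetylhexosamine
(HexNAc: GlcNAc), deoxyhexose (dHex: fucose) and N-acetylneuraminic acid
(NeuAc: sialic acid) — because MS of intact glycans cannot resolve isomeric
structures.  This module provides the composition type, its canonical string
form ``H#N#[F#][S#]``, theoretical monoisotopic masses, the sodiated-ion m/z
used for peak annotation (MALDI of underivatized glycans with NaCl doping
yields predominantly the singly charged [M+Na]+ species), a composition-based
structural classification (high-mannose / hybrid / complex) and an exhaustive
enumerator over an m/z window.

The structural class is assigned from the composition alone:

* ``hexnac == 2``, ``hex >= 5``, no fucose, no sialic acid → high-mannose
  (the Man5–Man9 series on the chitobiose core);
* ``hexnac >= 4`` → complex (two or more antennary GlcNAcs);
* ``hexnac == 3`` with ``hex >= 5`` → hybrid (one antennary GlcNAc plus
  retained mannose arms);
* every other valid composition (paucimannose, truncated species) → complex.

This rule is a documented convention: composition-level data cannot prove a
structure, and users with orthogonal structural evidence can override the
class in a custom trait catalog.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Iterator, Sequence

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "parse_composition",
    "monoisotopic_mass",
    "sodiated_mz",
    "classify_glycan",
    "enumerate_compositions",
    "default_registry",
    "MASS_HEX",
    "MASS_HEXNAC",
    "MASS_DHEX",
    "MASS_NEUAC",
    "MASS_H2O",
    "MASS_NA_CATION",
]

# Residue monoisotopic masses in Da (standard glycomics constants; each is the
# elemental monoisotopic mass of the dehydrated residue).
MASS_HEX = 162.05282  # C6H10O5
MASS_HEXNAC = 203.07937  # C8H13NO5
MASS_DHEX = 146.05791  # C6H10O4
MASS_NEUAC = 291.09542  # C11H17NO8
MASS_H2O = 18.01056
# Sodium cation: atomic Na 22.98977 minus one electron mass.
MASS_NA_CATION = 22.98922

_COMPOSITION_RE = re.compile(r"^H(\d+)N(\d+)(?:F(\d+))?(?:S(\d+))?$")


@dataclass(frozen=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan composition.

    Parameters
    ----------
    hex : int
        Number of hexose residues (mannose + galactose).
    hexnac : int
        Number of N-acetylhexosamine residues (GlcNAc).
    dhex : int
        Number of deoxyhexose (fucose) residues.
    neuac : int
        Number of N-acetylneuraminic (sialic) acid residues.
    """

    hex: int
    hexnac: int
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for field in ("hex", "hexnac", "dhex", "neuac"):
            value = getattr(self, field)
            if not isinstance(value, int) or value < 0:
                raise ValueError(
                    f"{field} count must be a non-negative integer, got {value!r}"
                )

    @property
    def is_valid(self) -> bool:
        """True if the counts describe a plausible N-glycan.

        Requires the chitobiose core plus trimannosyl arms (hexnac >= 2,
        hex >= 3) and no more fucoses than HexNAc attachment sites.
        """
        return self.hexnac >= 2 and self.hex >= 3 and self.dhex <= self.hexnac

    def validate(self) -> "GlycanComposition":
        if not self.is_valid:
            raise ValueError(
                f"{self!s} is not a valid N-glycan composition: requires "
                "hexnac >= 2 and hex >= 3 (chitobiose core + trimannosyl) "
                "and dhex <= hexnac (one fucose per HexNAc)"
            )
        return self

    def __str__(self) -> str:
        text = f"H{self.hex}N{self.hexnac}"
        if self.dhex:
            text += f"F{self.dhex}"
        if self.neuac:
            text += f"S{self.neuac}"
        return text


@dataclass(frozen=True)
class GlycanClass:
    """Structural and charge class of a composition."""

    structural: str  # one of {"high_mannose", "hybrid", "complex"}
    charge: str  # one of {"neutral", "sialylated"}


def parse_composition(text: str) -> GlycanComposition:
    """Parse a canonical composition string ``H#N#[F#][S#]``.

    Omitted F/S blocks parse as zero.  Raises ``ValueError`` for malformed
    strings or compositions that violate N-glycan validity.
    """
    match = _COMPOSITION_RE.match(text.strip())
    if match is None:
        raise ValueError(
            f"malformed composition string {text!r}: expected H#N#[F#][S#]"
        )
    hex_, hexnac, dhex, neuac = (int(g) if g is not None else 0 for g in match.groups())
    return GlycanComposition(hex_, hexnac, dhex, neuac).validate()


def _as_composition(comp: "GlycanComposition | str") -> GlycanComposition:
    if isinstance(comp, str):
        return parse_composition(comp)
    return comp.validate()


def monoisotopic_mass(comp: "GlycanComposition | str") -> float:
    """Monoisotopic mass of the neutral glycan molecule in Da.

    The mass is the sum of dehydrated residue masses plus one water for the
    reducing end, so it is exactly additive in the residue counts.
    """
    comp = _as_composition(comp)
    return (
        comp.hex * MASS_HEX
        + comp.hexnac * MASS_HEXNAC
        + comp.dhex * MASS_DHEX
        + comp.neuac * MASS_NEUAC
        + MASS_H2O
    )


def sodiated_mz(comp: "GlycanComposition | str") -> float:
    """m/z of the singly charged sodiated ion [M+Na]+."""
    return monoisotopic_mass(comp) + MASS_NA_CATION


def classify_glycan(comp: "GlycanComposition | str") -> GlycanClass:
    """Assign the structural and charge class of a valid composition.

    See the module docstring for the composition-based rule; the charge label
    is ``sialylated`` iff at least one NeuAc is present.
    """
    comp = _as_composition(comp)
    if comp.hexnac == 2 and comp.hex >= 5 and comp.dhex == 0 and comp.neuac == 0:
        structural = "high_mannose"
    elif comp.hexnac >= 4:
        structural = "complex"
    elif comp.hexnac == 3 and comp.hex >= 5:
        structural = "hybrid"
    else:
        structural = "complex"
    charge = "sialylated" if comp.neuac >= 1 else "neutral"
    return GlycanClass(structural=structural, charge=charge)


def enumerate_compositions(
    mz_low: float,
    mz_high: float,
    bounds: Sequence[int] = (10, 10, 5, 5),
) -> list[GlycanComposition]:
    """Enumerate all valid compositions whose [M+Na]+ m/z falls in a window.

    Parameters
    ----------
    mz_low, mz_high : float
        Inclusive m/z window in Da.
    bounds : sequence of 4 ints
        Maximum counts for (hex, hexnac, dhex, neuac).

    Returns
    -------
    list of GlycanComposition, sorted by sodiated m/z ascending.
    """
    import math

    if not (math.isfinite(mz_low) and math.isfinite(mz_high)):
        raise ValueError("m/z window bounds must be finite")
    if mz_low >= mz_high:
        raise ValueError(f"empty m/z window [{mz_low}, {mz_high}]")
    if any((not isinstance(b, int)) or b < 0 for b in bounds) or len(bounds) != 4:
        raise ValueError("bounds must be four non-negative integers")

    hex_max, hexnac_max, dhex_max, neuac_max = bounds
    base = MASS_H2O + MASS_NA_CATION
    out: list[GlycanComposition] = []
    for h in range(3, hex_max + 1):
        mh = base + h * MASS_HEX
        if mh > mz_high:
            break
        for n in range(2, hexnac_max + 1):
            mn = mh + n * MASS_HEXNAC
            if mn > mz_high:
                break
            for f in range(0, min(dhex_max, n) + 1):
                mf = mn + f * MASS_DHEX
                if mf > mz_high:
                    break
                for s in range(0, neuac_max + 1):
                    mz = mf + s * MASS_NEUAC
                    if mz > mz_high:
                        break
                    if mz >= mz_low:
                        out.append(GlycanComposition(h, n, f, s))
    out.sort(key=sodiated_mz)
    return out


def default_registry() -> list[GlycanComposition]:
    """The bundled 27-composition annotation target list.

    A plausible serum N-glycome panel spanning the high-mannose series,
    hybrid species and neutral/fucosylated/sialylated complex glycans; it is
    the default target list for peak annotation and is user-replaceable
    (``load_registry``).
    """
    text = resources.files("glycopanel.data").joinpath("registry.txt").read_text()
    return _parse_registry_lines(text.splitlines())


def load_registry(path) -> list[GlycanComposition]:
    """Load an annotation target list: one composition string per line."""
    with open(path, "r", encoding="utf-8") as handle:
        return _parse_registry_lines(handle)


def _parse_registry_lines(lines: Iterable[str]) -> list[GlycanComposition]:
    comps: list[GlycanComposition] = []
    seen: set[str] = set()
    for line in lines:
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        comp = parse_composition(line)
        if str(comp) in seen:
            raise ValueError(f"duplicate registry composition {comp}")
        seen.add(str(comp))
        comps.append(comp)
    return comps
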