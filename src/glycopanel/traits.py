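"""Derived glycan traits: a declarative catalog evaluated over fractions.

A derived trait (IGP) is a ratio of sums of normalized glycan fractions over
two composition subsets — e.g. total fucosylation is the summed fraction of
all fucose-carrying glycans.  Subsets are selected by small declarative
predicates over the composition attributes ``hex, hexnac, dhex, neuac`` and
the class labels ``structural`` ("high_mannose" | "hybrid" | "complex") and
``charge`` ("neutral" | "sialylated").  Predicates are data, not code: the
expression language admits only attribute comparisons, integer/string
constants and ``and`` / ``or`` / ``not`` (validated on an AST whitelist), so
catalogs stay auditable and portable.

Two transforms exist:

* ``fraction`` — numerator subset ⊆ denominator subset (denominator may be
  ``total`` = all quantified glycans); values lie in [0, 1].
* ``ratio`` — a free ratio of two disjoint subsets (e.g. neutral:sialylated);
  unbounded above.

A zero denominator yields a missing value (NaN), never zero and never an
error.  The bundled default catalog defines 47 traits, IGP28–IGP74; it is
this package's own documented trait set — studies with their own formula
sheets reproduce them exactly by supplying a replacement catalog.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .compositions import GlycanComposition, classify_glycan, _as_composition
from .spectra import CohortManifest, CLINICAL_COLUMNS

__all__ = [
    "TraitDefinition",
    "load_trait_catalog",
    "default_trait_catalog",
    "compile_predicate",
    "evaluate_trait",
    "evaluate_catalog",
    "build_feature_table",
]

_ALLOWED_ATTRS = ("hex", "hexnac", "dhex", "neuac", "structural", "charge")

_ALLOWED_NODES = (
    ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp, ast.Not,
    ast.Compare, ast.Name, ast.Load, ast.Constant,
    ast.Eq, ast.NotEq, ast.Lt, ast.LtE, ast.Gt, ast.GtE,
)


def compile_predicate(expr: str) -> Callable[[Mapping[str, object]], bool]:
    """Compile a predicate string into a function of composition attributes.

    Only comparisons of the attributes ``hex, hexnac, dhex, neuac,
    structural, charge`` against integer or string constants, combined with
    ``and``/``or``/``not``, are accepted.
    """
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"unparseable predicate {expr!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ValueError(
                f"predicate {expr!r} uses disallowed syntax {type(node).__name__}"
            )
        if isinstance(node, ast.Name) and node.id not in _ALLOWED_ATTRS:
            raise ValueError(
                f"predicate {expr!r} references unknown attribute {node.id!r}; "
                f"allowed: {_ALLOWED_ATTRS}"
            )
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, str)):
            raise ValueError(f"predicate {expr!r}: only int/str constants allowed")
    code = compile(tree, "<trait predicate>", "eval")

    def predicate(attrs: Mapping[str, object]) -> bool:
        return bool(eval(code, {"__builtins__": {}}, dict(attrs)))

    return predicate


def composition_attributes(comp: "GlycanComposition | str") -> dict[str, object]:
    comp = _as_composition(comp)
    klass = classify_glycan(comp)
    return {
        "hex": comp.hex,
        "hexnac": comp.hexnac,
        "dhex": comp.dhex,
        "neuac": comp.neuac,
        "structural": klass.structural,
        "charge": klass.charge,
    }


@dataclass(frozen=True)
class TraitDefinition:
    """One derived glycan trait.

    Attributes
    ----------
    igp_id : str
        Catalog label, e.g. ``IGP33``.
    name : str
        Human-readable description.
    numerator : str
        Predicate selecting the numerator composition subset.
    denominator : str
        Predicate for the denominator subset, or the keyword ``total``.
    transform : {"fraction", "ratio"}
        ``fraction`` requires numerator ⊆ denominator; ``ratio`` is free.
    """

    igp_id: str
    name: str
    numerator: str
    denominator: str = "total"
    transform: str = "fraction"

    def __post_init__(self) -> None:
        if self.transform not in ("fraction", "ratio"):
            raise ValueError(f"{self.igp_id}: unknown transform {self.transform!r}")
        compile_predicate(self.numerator)
        if self.denominator != "total":
            compile_predicate(self.denominator)

    def masks(self, compositions: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (numerator, denominator) membership over a composition list."""
        attrs = [composition_attributes(c) for c in compositions]
        num_fn = compile_predicate(self.numerator)
        num = np.array([num_fn(a) for a in attrs], dtype=bool)
        if self.denominator == "total":
            den = np.ones(len(attrs), dtype=bool)
        else:
            den_fn = compile_predicate(self.denominator)
            den = np.array([den_fn(a) for a in attrs], dtype=bool)
        if self.transform == "fraction" and np.any(num & ~den):
            raise ValueError(
                f"{self.igp_id}: numerator subset must lie within the denominator "
                "for fraction-type traits"
            )
        return num, den


def _catalog_from_entries(entries: Iterable[Mapping[str, object]]) -> list[TraitDefinition]:
    catalog: list[TraitDefinition] = []
    seen: set[str] = set()
    for entry in entries:
        trait = TraitDefinition(
            igp_id=str(entry["igp_id"]),
            name=str(entry.get("name", entry["igp_id"])),
            numerator=str(entry["numerator"]),
            denominator=str(entry.get("denominator", "total")),
            transform=str(entry.get("transform", "fraction")),
        )
        if trait.igp_id in seen:
            raise ValueError(f"duplicate trait id {trait.igp_id}")
        seen.add(trait.igp_id)
        catalog.append(trait)
    return catalog


def load_trait_catalog(path) -> list[TraitDefinition]:
    """Load a YAML trait catalog (list of trait mappings)."""
    with open(path, "r", encoding="utf-8") as handle:
        entries = yaml.safe_load(handle)
    if entries is None:
        return []
    if not isinstance(entries, list):
        raise ValueError("trait catalog must be a YAML list of trait entries")
    return _catalog_from_entries(entries)


def default_trait_catalog() -> list[TraitDefinition]:
    """The bundled default catalog: 47 derived traits, IGP28–IGP74."""
    text = resources.files("glycopanel.data").joinpath("traits.yaml").read_text()
    return _catalog_from_entries(yaml.safe_load(text))


def evaluate_trait(trait: TraitDefinition, fractions: pd.DataFrame) -> pd.Series:
    """Evaluate one trait over a samples × compositions fraction table.

    Returns a Series per sample: Σ numerator fractions / Σ denominator
    fractions (denominator ``total`` ≡ the full row sum, which is 1 for a
    normalized table).  Zero denominators propagate as NaN.
    """
    num_mask, den_mask = trait.masks(list(fractions.columns))
    num = fractions.loc[:, num_mask].sum(axis=1)
    den = fractions.loc[:, den_mask].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = num / den
    values[den == 0] = np.nan
    values.name = trait.igp_id
    return values


def evaluate_catalog(catalog: Sequence[TraitDefinition], fractions: pd.DataFrame) -> pd.DataFrame:
    if not catalog:
        return pd.DataFrame(index=fractions.index)
    return pd.concat([evaluate_trait(t, fractions) for t in catalog], axis=1)


def build_feature_table(
    fractions: pd.DataFrame,
    catalog: Sequence[TraitDefinition],
    manifest: CohortManifest | None = None,
    igp_prefix: bool = True,
) -> pd.DataFrame:
    """Assemble the full IGP feature table.

    Columns are the quantified glycan fractions in registry order — renamed
    IGP1..IGPk when ``igp_prefix`` — followed by the derived traits in
    catalog order, then a ``group`` column and any clinical covariates from
    the manifest.  The glycan→IGP renumbering is recorded in the returned
    table's ``attrs["igp_map"]``.
    """
    quant = fractions.copy()
    igp_map = {f"IGP{i + 1}": c for i, c in enumerate(quant.columns)} if igp_prefix else {}
    if igp_prefix:
        quant.columns = list(igp_map)
    derived = evaluate_catalog(catalog, fractions)
    clash = set(quant.columns) & set(derived.columns)
    if clash:
        raise ValueError(f"derived trait ids collide with quantified columns: {sorted(clash)}")
    table = pd.concat([quant, derived], axis=1)
    table.attrs["feature_columns"] = list(table.columns)
    table.attrs["igp_map"] = igp_map
    if manifest is not None:
        meta = manifest.samples.set_index("sample_id")
        missing = set(table.index) ^ set(meta.index)
        if missing:
            raise ValueError(f"manifest/quantification sample mismatch: {sorted(missing)}")
        meta = meta.loc[table.index]
        table["group"] = meta["group"]
        for col in CLINICAL_COLUMNS:
            if col in meta.columns:
                table[col] = meta[col]
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The glycan feature columns of a feature table (no group/clinical)."""
    cols = table.attrs.get("feature_columns")
    if cols is not None:
        return [c for c in cols if c in table.columns]
    drop = {"group", *CLINICAL_COLUMNS}
    return [c for c in table.columns if c not in drop]
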