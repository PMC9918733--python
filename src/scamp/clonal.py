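"""Driver-based clone assignment, genotype colocalization, feature matrices.

Clones in targeted single-cell DNA-seq are defined by simple genotype rules
over bulk-validated drivers: a tumor clone by carriage of the clonal driver
(e.g. the KRAS hotspot variant), a "putative normal" population by wildtype
calls at every listed variant. Rules are evaluated in order; the first match
wins; MISSING calls satisfy neither carrier nor wildtype requirements.

Colocalization (Venn) counts over 2-3 variants reveal co-occurring versus
mutually exclusive clones; cells MISSING at any queried variant are excluded
and reported. The combined SNV-genotype + per-amplicon homozygous-deletion
feature matrix is the input for multi-layer multi-state clustering of clonal
architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .types import Genotype, GenotypeMatrix, ValidationError, VariantId

__all__ = [
    "CloneRule",
    "CloneAssignment",
    "VennCounts",
    "MultiLayerFeatures",
    "assign_clones",
    "colocalization_counts",
    "build_multilayer_features",
    "format_percent",
]


@dataclass(frozen=True)
class CloneRule:
    """One clone-defining rule over driver genotypes.

    ``required_carriers``: the cell must carry (HET/HOM) these variants —
    all of them by default, or at least one if ``any_of_carriers`` is set
    (for clones defined by "carrying at least one of" several drivers).
    ``required_wt``: the cell must have an explicit WT call at each.
    """

    clone_id: str
    required_carriers: frozenset[VariantId] = frozenset()
    required_wt: frozenset[VariantId] = frozenset()
    any_of_carriers: bool = False

    def __post_init__(self) -> None:
        if self.required_carriers & self.required_wt:
            raise ValidationError(
                f"rule {self.clone_id!r}: carrier and WT sets overlap"
            )
        if not self.required_carriers and not self.required_wt:
            raise ValidationError(f"rule {self.clone_id!r} is empty")


@dataclass
class CloneAssignment:
    assignments: dict[str, str]  # cell -> clone_id or "unassigned"
    counts: dict[str, int]
    fractions: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "clone": z,
                "n_cells": self.counts[z],
                "fraction": self.fractions[z],
                "percent": format_percent(self.fractions[z]),
            }
            for z in self.counts
        ]
        return pd.DataFrame(rows)


def format_percent(fraction: float) -> str:
    """Render a clone fraction the way such results are conventionally printed:
    one decimal place, except fractions under 2% which round to the nearest
    whole percent."""
    pct = 100.0 * fraction
    if pct < 2.0:
        return f"{round(pct):d}%"
    return f"{pct:.1f}%"


def _rule_matches(g: GenotypeMatrix, rule: CloneRule) -> np.ndarray:
    ok = np.ones(g.n_cells, dtype=bool)
    if rule.required_carriers:
        masks = [g.carrier_mask(v) for v in sorted(rule.required_carriers)]
        stacked = np.column_stack(masks)
        ok &= stacked.any(axis=1) if rule.any_of_carriers else stacked.all(axis=1)
    for v in sorted(rule.required_wt):
        ok &= g.column(v) == Genotype.WT
    return ok


def assign_clones(g: GenotypeMatrix, rules: list[CloneRule]) -> CloneAssignment:
    """Assign every cell to the first matching rule, else "unassigned"."""
    if not rules:
        raise ValidationError("no clone rules given")
    for rule in rules:
        for v in rule.required_carriers | rule.required_wt:
            if v not in g.variants:
                raise ValidationError(f"rule {rule.clone_id!r}: variant {v} not in matrix")
    assigned = np.full(g.n_cells, "unassigned", dtype=object)
    free = np.ones(g.n_cells, dtype=bool)
    for rule in rules:
        hit = _rule_matches(g, rule) & free
        assigned[hit] = rule.clone_id
        free &= ~hit
    n = g.n_cells
    clone_ids = [r.clone_id for r in rules] + ["unassigned"]
    counts = {z: int((assigned == z).sum()) for z in clone_ids}
    fractions = {z: counts[z] / n for z in clone_ids}
    return CloneAssignment(
        assignments=dict(zip(g.barcodes, assigned)),
        counts=counts,
        fractions=fractions,
    )


@dataclass
class VennCounts:
    """Carrier colocalization counts over 2-3 queried variants.

    ``regions`` maps each nonempty subset of the variants (as a frozenset) to
    the number of cells carrying exactly that subset. Cells MISSING at any
    queried variant are excluded and counted in ``n_excluded_missing``.
    Conservation: region counts + n_neither + n_excluded_missing = n_cells.
    """

    variants: list[VariantId]
    regions: dict[frozenset[VariantId], int]
    n_neither: int
    n_excluded_missing: int

    @property
    def n_cells(self) -> int:
        return sum(self.regions.values()) + self.n_neither + self.n_excluded_missing


def colocalization_counts(g: GenotypeMatrix, variants: list[VariantId]) -> VennCounts:
    """Venn-region carrier counts for 2-3 variants."""
    if len(variants) not in (2, 3):
        raise ValidationError("colocalization is defined for 2 or 3 variants")
    if len(set(variants)) != len(variants):
        raise ValidationError("duplicate variant ids in query")
    cols = np.column_stack([g.column(v) for v in variants])
    missing_any = (cols == Genotype.MISSING).any(axis=1)
    carrier = (cols == Genotype.HET) | (cols == Genotype.HOM)
    carrier[missing_any] = False
    regions: dict[frozenset[VariantId], int] = {}
    for r in range(1, len(variants) + 1):
        for combo in combinations(range(len(variants)), r):
            in_combo = np.zeros(len(variants), dtype=bool)
            in_combo[list(combo)] = True
            exact = (~missing_any) & (carrier == in_combo[None, :]).all(axis=1)
            regions[frozenset(variants[i] for i in combo)] = int(exact.sum())
    n_neither = int(((~missing_any) & ~carrier.any(axis=1)).sum())
    return VennCounts(
        variants=list(variants),
        regions=regions,
        n_neither=n_neither,
        n_excluded_missing=int(missing_any.sum()),
    )


@dataclass
class MultiLayerFeatures:
    """Combined genotype + homdel feature matrix for multi-state clustering."""

    cells: list[str]
    columns: list[str]
    provenance: list[str]  # "genotype" or "homdel" per column
    table: pd.DataFrame  # genotype columns hold Genotype names; homdel columns bool

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def build_multilayer_features(
    g: GenotypeMatrix,
    variants: list[VariantId],
    homdel: pd.DataFrame,
    amplicons: list[str],
) -> MultiLayerFeatures:
    """Concatenate selected variant genotypes with per-cell homdel indicators.

    ``homdel`` is a cell×amplicon boolean DataFrame (e.g. per-cell ploidy
    below the homdel cutoff). Genotypes are exported as 4-state categoricals
    (WT/HET/HOM/MISSING), homdel as booleans, in the declared column order.
    """
    if amplicons and set(g.barcodes) != set(homdel.index):
        raise ValidationError("genotype and homdel matrices index different cells")
    unknown = [a for a in amplicons if a not in homdel.columns]
    if unknown:
        raise ValidationError(f"amplicons not in homdel matrix: {unknown}")
    labels = np.array([x.name for x in Genotype])
    data: dict[str, object] = {}
    provenance: list[str] = []
    for v in variants:
        data[str(v)] = labels[g.column(v)]
        provenance.append("genotype")
    hd = homdel.loc[g.barcodes] if amplicons else None
    for a in amplicons:
        data[f"homdel:{a}"] = hd[a].to_numpy(dtype=bool)
        provenance.append("homdel")
    table = pd.DataFrame(data, index=g.barcodes)
    return MultiLayerFeatures(
        cells=list(g.barcodes),
        columns=list(table.columns),
        provenance=provenance,
        table=table,
    )
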