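"""Per-cell genotype assignment, stringent variant filtering, pseudobulk VAF.

Genotyping is threshold-based and intended for bulk-validated variants, not
novel SNV discovery. Per cell-variant pair:

* depth DP below ``min_depth`` (default 5) → MISSING;
* otherwise bin the percent VAF = 100·AD/DP into
  WT ∈ [0, 20], HET ∈ (20, 80], HOM ∈ (80, 100];
* finally demote HET/HOM calls with fewer than ``min_alt`` (default 3)
  alternate reads back to WT (low-alt calls are likely artifacts of
  misalignment, homopolymers or droplet merging).

The demotion rule is applied to both HET and HOM calls; the same AD cutoff
governs both (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    CellVariantData,
    ConfigError,
    Genotype,
    GenotypeMatrix,
    ValidationError,
    VariantId,
)

__all__ = [
    "GenotypeParams",
    "VariantFilterParams",
    "assign_genotypes",
    "filter_high_quality_variants",
    "pseudobulk_vaf",
]


@dataclass(frozen=True)
class GenotypeParams:
    min_depth: int = 5
    min_alt: int = 3
    vaf_wt_max: float = 20.0  # percent
    vaf_het_max: float = 80.0  # percent

    def __post_init__(self) -> None:
        if not (0 < self.vaf_wt_max < self.vaf_het_max <= 100):
            raise ConfigError("require 0 < vaf_wt_max < vaf_het_max <= 100")
        if self.min_depth < 1:
            raise ConfigError("min_depth must be >= 1")
        if self.min_alt < 0:
            raise ConfigError("min_alt must be >= 0")


@dataclass(frozen=True)
class VariantFilterParams:
    """Stringent de-novo variant filter (re-genotype, missingness, prevalence)."""

    strict_min_depth: int = 10
    strict_min_alt: int = 5
    max_missing_fraction: float = 0.75
    whitelist_genes: frozenset[str] = frozenset({"SMAD4", "CDKN2A"})
    min_prevalence: float = 0.005

    def __post_init__(self) -> None:
        if not (0.0 < self.max_missing_fraction < 1.0):
            raise ConfigError("max_missing_fraction must be in (0,1)")
        if not (0.0 < self.min_prevalence < 1.0):
            raise ConfigError("min_prevalence must be in (0,1)")


def assign_genotypes(d: CellVariantData, p: GenotypeParams = GenotypeParams()) -> GenotypeMatrix:
    """Assign WT/HET/HOM/MISSING to every cell-variant pair. Pure function."""
    dp = d.DP
    ad = d.AD
    calls = np.full(dp.shape, np.int8(Genotype.WT))
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf = np.where(dp > 0, 100.0 * ad / np.maximum(dp, 1), 0.0)
    calls[vaf > p.vaf_wt_max] = np.int8(Genotype.HET)
    calls[vaf > p.vaf_het_max] = np.int8(Genotype.HOM)
    low_alt = (ad < p.min_alt) & (
        (calls == Genotype.HET) | (calls == Genotype.HOM)
    )
    calls[low_alt] = np.int8(Genotype.WT)
    calls[dp < p.min_depth] = np.int8(Genotype.MISSING)
    return GenotypeMatrix(barcodes=d.barcodes, variants=d.variants, calls=calls)


def filter_high_quality_variants(
    d: CellVariantData,
    p: VariantFilterParams = VariantFilterParams(),
    gene_map: dict[VariantId, str] | None = None,
) -> list[VariantId]:
    """Derive the de-novo high-quality variant list from raw counts.

    Steps: (1) re-genotype with the stringent depth/alt thresholds (same VAF
    bins); (2) discard variants MISSING in strictly more than
    ``max_missing_fraction`` of cells, unless their gene is whitelisted
    (genes prone to homozygous deletion would otherwise be lost to
    missingness); (3) keep variants carried (HET or HOM) by at least
    ``min_prevalence`` of all cells. Ordered by prevalence descending, ties
    by canonical variant string.
    """
    if d.n_cells == 0:
        raise ValidationError("no cells")
    gene_map = gene_map or {}
    strict = assign_genotypes(
        d,
        GenotypeParams(min_depth=p.strict_min_depth, min_alt=p.strict_min_alt),
    )
    n = d.n_cells
    missing_frac = (strict.calls == Genotype.MISSING).mean(axis=0)
    carrier_frac = (
        (strict.calls == Genotype.HET) | (strict.calls == Genotype.HOM)
    ).sum(axis=0) / n
    kept: list[tuple[float, str, VariantId]] = []
    for j, v in enumerate(d.variants):
        whitelisted = gene_map.get(v) in p.whitelist_genes
        if missing_frac[j] > p.max_missing_fraction and not whitelisted:
            continue
        if carrier_frac[j] >= p.min_prevalence:
            kept.append((float(carrier_frac[j]), str(v), v))
    kept.sort(key=lambda t: (-t[0], t[1]))
    return [v for _, _, v in kept]


def pseudobulk_vaf(d: CellVariantData, cells: list[str] | None = None) -> dict[VariantId, float]:
    """Read-weighted aggregate VAF per variant over a cell subset.

    Sum of alternate reads over cells divided by sum of total reads — the
    quantity comparable with a bulk measurement of the same material.
    Variants with zero total depth in the subset are undefined and omitted.
    """
    if cells is None:
        sub = d
    else:
        if not cells:
            raise ValidationError("empty cell subset")
        missing = set(cells) - set(d.barcodes)
        if missing:
            raise ValidationError(f"cells not in data: {sorted(missing)[:5]}")
        sub = d.subset_cells(cells)
    dp_sum = sub.DP.sum(axis=0)
    ad_sum = sub.AD.sum(axis=0)
    return {
        v: float(ad_sum[j] / dp_sum[j])
        for j, v in enumerate(sub.variants)
        if dp_sum[j] > 0
    }
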