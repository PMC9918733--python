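"""Library-level QC metrics: allelic dropout and sequencing-depth planning.

Allelic dropout (ADO) is the failure to amplify one of the two alleles at a
truly heterozygous site, producing a spuriously homozygous single-cell
observation. It is estimated from germline SNPs — sites expected HET in every
nucleus — as, per SNP,

    ADO = (# nuclei with strictly 0 reads of exactly one allele)
          / (# nuclei measured at that SNP)

and averaged (unweighted) over SNPs. Nuclei with zero reads of *both*
alleles are unobservable at the site and enter neither numerator nor
denominator; the denominator requires a minimum depth (default 5) so that a
zero-read allele is evidence of dropout rather than shallow sampling.

Depth planning uses the standard read-budget identity for droplet amplicon
sequencing: required total read pairs =
(expected nuclei called) × (amplicons) × (target depth per cell per
amplicon) ÷ (expected fraction of reads assigned to cells).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import BulkAnnotation, CellVariantData, ConfigError, ValidationError, VariantId

__all__ = [
    "SnpSelectionParams",
    "ADOResult",
    "DepthPlanParams",
    "select_germline_snps",
    "compute_ado",
    "required_read_pairs",
    "expected_nuclei_called",
]


@dataclass(frozen=True)
class SnpSelectionParams:
    min_bulk_normal_vaf: float = 0.2
    sc_mean_vaf_low: float = 0.2
    sc_mean_vaf_high: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.sc_mean_vaf_low < self.sc_mean_vaf_high < 1.0):
            raise ConfigError("require 0 < low < high < 1 for single-cell mean VAF band")


@dataclass
class ADOResult:
    per_snp_ado: dict[VariantId, float]
    per_snp_denominator: dict[VariantId, int]
    mean_ado: float
    n_snps: int


@dataclass(frozen=True)
class DepthPlanParams:
    expected_nuclei: int
    n_amplicons: int
    target_depth: float = 100.0
    frac_reads_to_cells: float = 0.5

    def __post_init__(self) -> None:
        if self.expected_nuclei <= 0 or self.n_amplicons <= 0 or self.target_depth <= 0:
            raise ConfigError("nuclei, amplicons and target depth must be positive")
        if not (0.0 < self.frac_reads_to_cells <= 1.0):
            raise ConfigError("frac_reads_to_cells must be in (0,1]")


def select_germline_snps(
    d: CellVariantData,
    bulk: list[BulkAnnotation],
    p: SnpSelectionParams = SnpSelectionParams(),
) -> list[VariantId]:
    """Pick variants that behave like germline heterozygous SNPs.

    A variant qualifies if (a) it is detected in the matched bulk normal with
    VAF above ``min_bulk_normal_vaf`` (avoids technical artifacts), and (b)
    its mean single-nucleus VAF — computed over nuclei with nonzero VAF, so
    dropout of the alternate allele does not drag the mean down — lies
    strictly inside the (low, high) band, excluding homozygous sites and
    somatic mosaicism.
    """
    normals = [r for r in bulk if r.is_normal_sample]
    if not normals:
        raise ValidationError("no normal-sample bulk annotations provided")
    passing_bulk = {r.variant for r in normals if r.bulk_vaf > p.min_bulk_normal_vaf}
    out: list[VariantId] = []
    for j, v in enumerate(d.variants):
        if v not in passing_bulk:
            continue
        dp = d.DP[:, j]
        ad = d.AD[:, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            vaf = np.where(dp > 0, ad / np.maximum(dp, 1), 0.0)
        nonzero = vaf > 0
        if not nonzero.any():
            continue
        mean_vaf = float(vaf[nonzero].mean())
        if p.sc_mean_vaf_low < mean_vaf < p.sc_mean_vaf_high:
            out.append(v)
    return out


def compute_ado(
    d: CellVariantData,
    snps: list[VariantId],
    min_depth: int = 5,
) -> ADOResult:
    """Estimate the allelic-dropout rate from germline heterozygous SNPs.

    Per SNP, the denominator is the number of nuclei with DP ≥ ``min_depth``
    and the numerator those among them with exactly one allele at zero reads
    (AD = 0 xor AD = DP). SNPs with an empty denominator are excluded with a
    warning. ``mean_ado`` is the unweighted mean of per-SNP rates.
    """
    unknown = [v for v in snps if v not in d.variants]
    if unknown:
        raise ValidationError(f"SNPs not in data: {unknown[:5]}")
    per_snp: dict[VariantId, float] = {}
    denoms: dict[VariantId, int] = {}
    for v in snps:
        j = d.variant_index(v)
        dp = d.DP[:, j]
        ad = d.AD[:, j]
        mask = dp >= min_depth
        denom = int(mask.sum())
        if denom == 0:
            warnings.warn(f"SNP {v}: no nuclei with DP >= {min_depth}; excluded")
            continue
        ref = dp - ad
        one_allele_zero = mask & ((ad == 0) ^ (ref == 0))
        per_snp[v] = float(one_allele_zero.sum() / denom)
        denoms[v] = denom
    if not per_snp:
        raise ValidationError("no SNP had a nonzero denominator")
    mean_ado = float(np.mean(list(per_snp.values())))
    return ADOResult(
        per_snp_ado=per_snp,
        per_snp_denominator=denoms,
        mean_ado=mean_ado,
        n_snps=len(per_snp),
    )


def required_read_pairs(p: DepthPlanParams) -> int:
    """Total read pairs to order for a target per-cell per-amplicon depth."""
    x = p.expected_nuclei * p.n_amplicons * p.target_depth / p.frac_reads_to_cells
    return math.ceil(x)


def expected_nuclei_called(concentration_per_ul: float) -> int:
    """Expected nuclei called from the loading concentration (nuclei/µl × 1 µl)."""
    if concentration_per_ul < 0:
        raise ConfigError("concentration must be non-negative")
    return int(round(concentration_per_ul * 1.0))
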