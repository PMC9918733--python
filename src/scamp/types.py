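"""Core domain types for targeted single-cell amplicon DNA-seq data.

The fundamental substrates of the analysis are three aligned matrices per
library: a cell×variant total-depth matrix (DP), a cell×variant alternate-read
matrix (AD), and a barcode×amplicon read-count matrix, together with the
amplicon panel definition and (optionally) bulk-sequencing variant
annotations. All downstream stages — cell calling, genotyping, allelic-dropout
estimation, doublet inference, ploidy and clonal analysis — operate on these
containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "ScampError",
    "FormatError",
    "ValidationError",
    "ConfigError",
    "Genotype",
    "VariantId",
    "AmpliconPanel",
    "CellVariantData",
    "AmpliconMatrix",
    "BulkAnnotation",
    "GenotypeMatrix",
]


class ScampError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScampError):
    """A file or container does not have the expected structure."""


class ValidationError(ScampError):
    """Data violates a structural invariant (shapes, ranges, identities)."""


class ConfigError(ScampError):
    """A configuration value is inconsistent or out of its legal range."""


class Genotype(IntEnum):
    """Per-cell categorical genotype call at a variant site.

    ``MISSING`` marks cell-variant pairs whose read depth is below the calling
    threshold; it satisfies neither "carrier" nor "wildtype" requirements in
    clonal rules.
    """

    WT = 0
    HET = 1
    HOM = 2
    MISSING = 3

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM)


@dataclass(frozen=True, order=True)
class VariantId:
    """A variant site identified by chromosome, 1-based position and alleles.

    The canonical string form is ``"chrom:pos:ref/alt"`` and round-trips
    through :meth:`from_string`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref and alt alleles are identical: {self.ref!r}")
        if self.pos < 1:
            raise ValidationError(f"position must be 1-based positive, got {self.pos}")

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}/{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "VariantId":
        try:
            chrom, pos, alleles = s.split(":")
            ref, alt = alleles.split("/")
        except ValueError as exc:
            raise FormatError(f"cannot parse variant id {s!r}") from exc
        return cls(chrom=chrom, pos=int(pos), ref=ref, alt=alt)


@dataclass
class AmpliconPanel:
    """The targeted PCR amplicon panel: one genomic interval per amplicon.

    Coordinates are 1-based inclusive (MAF convention). A panel in this
    workflow is a couple of hundred ~200 bp amplicons tiling mutational
    hotspots and frequently deleted genes.
    """

    table: pd.DataFrame  # columns: amplicon_id, chrom, start, end, gene

    REQUIRED = ("amplicon_id", "chrom", "start", "end", "gene")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"panel table missing columns: {missing}")
        if len(self.table) == 0:
            raise ValidationError("amplicon panel is empty")
        if self.table["amplicon_id"].duplicated().any():
            dups = self.table["amplicon_id"][self.table["amplicon_id"].duplicated()]
            raise ValidationError(f"duplicate amplicon ids: {sorted(set(dups))}")
        bad = self.table["start"] > self.table["end"]
        if bad.any():
            raise ValidationError(
                f"start > end for amplicons: {list(self.table.loc[bad, 'amplicon_id'])}"
            )
        self.table = self.table.reset_index(drop=True)

    @property
    def amplicon_ids(self) -> list[str]:
        return list(self.table["amplicon_id"])

    def __len__(self) -> int:
        return len(self.table)

    def gene_of(self, amplicon_id: str) -> str:
        row = self.table.loc[self.table["amplicon_id"] == amplicon_id]
        if row.empty:
            raise KeyError(amplicon_id)
        return str(row["gene"].iloc[0])

    def covering_amplicon(self, variant: VariantId) -> str | None:
        """Return the id of the amplicon covering ``variant``, or None.

        If several amplicons overlap the position the first in panel order is
        returned (panels are designed non-overlapping per target).
        """
        t = self.table
        hit = t[(t["chrom"] == variant.chrom) & (t["start"] <= variant.pos) & (variant.pos <= t["end"])]
        if hit.empty:
            return None
        return str(hit["amplicon_id"].iloc[0])

    def amplicons_of_gene(self, gene: str) -> list[str]:
        return list(self.table.loc[self.table["gene"] == gene, "amplicon_id"])


def _check_unique(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class CellVariantData:
    """Per-barcode, per-variant read-count matrices (DP total, AD alternate)."""

    barcodes: list[str]
    variants: list[VariantId]
    DP: np.ndarray  # (n_barcodes, n_variants) non-negative int
    AD: np.ndarray  # (n_barcodes, n_variants) non-negative int

    def __post_init__(self) -> None:
        self.barcodes = list(self.barcodes)
        self.variants = list(self.variants)
        self.DP = np.asarray(self.DP, dtype=np.int64)
        self.AD = np.asarray(self.AD, dtype=np.int64)
        _check_unique(self.barcodes, "barcodes")
        shape = (len(self.barcodes), len(self.variants))
        if self.DP.shape != shape or self.AD.shape != shape:
            raise ValidationError(
                f"matrix shapes {self.DP.shape}/{self.AD.shape} disagree with index "
                f"lists {shape}"
            )
        if (self.DP < 0).any() or (self.AD < 0).any():
            raise ValidationError("negative read counts")
        bad = self.AD > self.DP
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"AD > DP at barcode {self.barcodes[i]!r}, variant "
                f"{self.variants[j]} (AD={self.AD[i, j]}, DP={self.DP[i, j]})"
            )

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant: VariantId) -> int:
        try:
            return self.variants.index(variant)
        except ValueError:
            raise KeyError(f"variant {variant} not in data") from None

    def subset_cells(self, barcodes: list[str]) -> "CellVariantData":
        idx = [self.barcodes.index(b) for b in barcodes]
        return CellVariantData(
            barcodes=[self.barcodes[i] for i in idx],
            variants=self.variants,
            DP=self.DP[idx],
            AD=self.AD[idx],
        )


@dataclass
class AmpliconMatrix:
    """Per-barcode, per-amplicon read counts (the cell-calling/ploidy substrate)."""

    barcodes: list[str]
    amplicons: list[str]
    counts: np.ndarray  # (n_barcodes, n_amplicons) non-negative int

    def __post_init__(self) -> None:
        self.barcodes = list(self.barcodes)
        self.amplicons = list(self.amplicons)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        _check_unique(self.barcodes, "barcodes")
        _check_unique(self.amplicons, "amplicon ids")
        shape = (len(self.barcodes), len(self.amplicons))
        if self.counts.shape != shape:
            raise ValidationError(f"counts shape {self.counts.shape} != {shape}")
        if (self.counts < 0).any():
            raise ValidationError("negative amplicon counts")

    @property
    def n_barcodes(self) -> int:
        return len(self.barcodes)

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    def total_reads(self) -> np.ndarray:
        """Per-barcode total reads across the panel."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.barcodes, columns=self.amplicons)

    def subset_barcodes(self, barcodes: list[str]) -> "AmpliconMatrix":
        idx = [self.barcodes.index(b) for b in barcodes]
        return AmpliconMatrix(
            barcodes=[self.barcodes[i] for i in idx],
            amplicons=self.amplicons,
            counts=self.counts[idx],
        )


@dataclass(frozen=True)
class BulkAnnotation:
    """One bulk-sequencing measurement of a variant (MAF-like "fillout" row)."""

    variant: VariantId
    sample_id: str
    bulk_vaf: float
    alt_reads: int
    total_reads: int
    is_normal_sample: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.bulk_vaf <= 1.0):
            raise ValidationError(
                f"bulk VAF {self.bulk_vaf} outside [0,1] for {self.variant}"
            )
        if self.total_reads > 0:
            implied = self.alt_reads / self.total_reads
            if abs(implied - self.bulk_vaf) > 0.01:
                raise ValidationError(
                    f"bulk VAF {self.bulk_vaf:.4f} inconsistent with "
                    f"{self.alt_reads}/{self.total_reads} for {self.variant}"
                )


@dataclass
class GenotypeMatrix:
    """Cell×variant categorical genotype calls in {WT, HET, HOM, MISSING}."""

    barcodes: list[str]
    variants: list[VariantId]
    calls: np.ndarray  # (n_cells, n_variants) int8 of Genotype values

    def __post_init__(self) -> None:
        self.barcodes = list(self.barcodes)
        self.variants = list(self.variants)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        shape = (len(self.barcodes), len(self.variants))
        if self.calls.shape != shape:
            raise ValidationError(f"calls shape {self.calls.shape} != {shape}")
        if not np.isin(self.calls, [g.value for g in Genotype]).all():
            raise ValidationError("calls contain values outside the genotype alphabet")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def column(self, variant: VariantId) -> np.ndarray:
        try:
            j = self.variants.index(variant)
        except ValueError:
            raise KeyError(f"variant {variant} not in genotype matrix") from None
        return self.calls[:, j]

    def carrier_mask(self, variant: VariantId) -> np.ndarray:
        """Boolean mask of cells with a HET or HOM call at ``variant``."""
        col = self.column(variant)
        return (col == Genotype.HET) | (col == Genotype.HOM)

    def to_frame(self) -> pd.DataFrame:
        labels = np.array([g.name for g in Genotype])
        return pd.DataFrame(
            labels[self.calls],
            index=self.barcodes,
            columns=[str(v) for v in self.variants],
        )
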