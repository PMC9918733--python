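"""Barcode quality control: selecting complete cells from raw barcode counts.

Droplet libraries emit reads for many more barcodes than real nuclei; most
barcodes are ambient/background with a small fraction of a real cell's reads.
Calling proceeds in three passes over the barcode×amplicon count matrix:

1. *Qualify* barcodes whose total reads strictly exceed
   ``total_read_multiplier × n_amplicons`` (default 8×).
2. Determine *working amplicons*: amplicons whose mean reads over qualified
   barcodes strictly exceed ``working_amplicon_factor`` (default 0.2) times
   the grand mean of those per-amplicon means.
3. Call as cells the qualified barcodes whose fraction of working amplicons
   with at least one read strictly exceeds ``completeness_fraction``
   (default 0.80).

All three thresholds are strict inequalities. "Data completeness" is read as
the fraction of working amplicons with nonzero reads for the barcode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AmpliconMatrix, ConfigError, ValidationError

__all__ = ["CellCallingParams", "CellCallingResult", "qualify_barcodes", "find_working_amplicons", "call_cells"]


@dataclass(frozen=True)
class CellCallingParams:
    total_read_multiplier: float = 8.0
    completeness_fraction: float = 0.80
    working_amplicon_factor: float = 0.2

    def __post_init__(self) -> None:
        if self.total_read_multiplier <= 0:
            raise ConfigError("total_read_multiplier must be positive")
        if not (0.0 < self.completeness_fraction <= 1.0):
            raise ConfigError("completeness_fraction must be in (0,1]")
        if not (0.0 < self.working_amplicon_factor <= 1.0):
            raise ConfigError("working_amplicon_factor must be in (0,1]")


@dataclass
class CellCallingResult:
    qualified_barcodes: set[str]
    working_amplicons: set[str]
    called_cells: list[str]  # ordered as in the input matrix
    diagnostics: pd.DataFrame  # index barcode; columns total_reads, completeness, called

    def __post_init__(self) -> None:
        if not set(self.called_cells) <= self.qualified_barcodes:
            raise ValidationError("called cells must be qualified barcodes")


def qualify_barcodes(m: AmpliconMatrix, params: CellCallingParams = CellCallingParams()) -> set[str]:
    """Barcodes with total reads strictly greater than multiplier × n_amplicons."""
    if m.n_barcodes == 0:
        raise ValidationError("empty amplicon matrix")
    threshold = params.total_read_multiplier * m.n_amplicons
    totals = m.total_reads()
    return {b for b, t in zip(m.barcodes, totals) if t > threshold}


def find_working_amplicons(
    m: AmpliconMatrix,
    qualified: set[str],
    params: CellCallingParams = CellCallingParams(),
) -> set[str]:
    """Amplicons whose mean reads over qualified barcodes beat the panel mean.

    An amplicon is working iff its per-qualified-barcode mean strictly
    exceeds ``working_amplicon_factor`` times the grand mean of all
    amplicons' means.
    """
    if not qualified:
        raise ValidationError("no qualified barcodes")
    rows = [i for i, b in enumerate(m.barcodes) if b in qualified]
    means = m.counts[rows].mean(axis=0)
    grand = means.mean()
    cutoff = params.working_amplicon_factor * grand
    return {a for a, mu in zip(m.amplicons, means) if mu > cutoff}


def call_cells(m: AmpliconMatrix, params: CellCallingParams = CellCallingParams()) -> CellCallingResult:
    """Run the full three-pass barcode QC and return calls with diagnostics."""
    qualified = qualify_barcodes(m, params)
    if not qualified:
        raise ValidationError("no barcodes pass the total-read threshold")
    working = find_working_amplicons(m, qualified, params)
    if not working:
        raise ValidationError("no working amplicons")
    w_cols = [k for k, a in enumerate(m.amplicons) if a in working]
    covered = (m.counts[:, w_cols] > 0).sum(axis=1) / len(w_cols)
    totals = m.total_reads()
    qualified_mask = np.array([b in qualified for b in m.barcodes])
    called_mask = qualified_mask & (covered > params.completeness_fraction)
    called = [b for b, c in zip(m.barcodes, called_mask) if c]
    diagnostics = pd.DataFrame(
        {
            "total_reads": totals,
            "completeness": covered,
            "qualified": qualified_mask,
            "called": called_mask,
        },
        index=m.barcodes,
    )
    return CellCallingResult(
        qualified_barcodes=qualified,
        working_amplicons=working,
        called_cells=called,
        diagnostics=diagnostics,
    )
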