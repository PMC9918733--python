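"""Per-amplicon ploidy from read counts, with homozygous-deletion detection.

Copy number of a ~200 bp amplicon in a cell is inferred from its read count
relative to a diploid baseline population, after a two-step normalization
that removes per-cell library size and per-amplicon PCR efficiency:

1. within each cell, divide by that cell's mean reads across amplicons;
2. within each amplicon, divide by the median of step-1 values over
   *good-quality* cells — cells with at least 1/10 of the total reads of
   the 10th-ranked cell by read count.

Ploidy is then ``2 × normalized / (baseline per-amplicon median of
normalized)``, where the baseline is a cell group believed diploid a priori
(e.g. cells wildtype for the clonal driver). Baseline cells therefore read
as ploidy 2 by construction; homozygous deletions appear as ploidy ≈ 0 and
are flagged below a configurable cutoff (default 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AmpliconMatrix, ConfigError, ValidationError

__all__ = [
    "PloidyParams",
    "PloidyMatrix",
    "good_quality_cells",
    "normalize_counts",
    "compute_ploidy",
    "clone_median_ploidy",
    "detect_homdel",
]


@dataclass(frozen=True)
class PloidyParams:
    good_cell_rank: int = 10
    good_cell_fraction: float = 0.1
    homdel_ploidy_max: float = 0.5

    def __post_init__(self) -> None:
        if self.good_cell_rank < 1:
            raise ConfigError("good_cell_rank must be >= 1")
        if not (0.0 < self.good_cell_fraction <= 1.0):
            raise ConfigError("good_cell_fraction must be in (0,1]")
        if not (0.0 <= self.homdel_ploidy_max < 1.0):
            raise ConfigError("homdel_ploidy_max must be in [0,1)")


@dataclass
class PloidyMatrix:
    cells: list[str]
    amplicons: list[str]
    ploidy: np.ndarray  # (n_cells, n_amplicons), NaN where undefined
    baseline_cells: set[str]

    def __post_init__(self) -> None:
        shape = (len(self.cells), len(self.amplicons))
        if self.ploidy.shape != shape:
            raise ValidationError(f"ploidy shape {self.ploidy.shape} != {shape}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ploidy, index=self.cells, columns=self.amplicons)


def good_quality_cells(m: AmpliconMatrix, p: PloidyParams = PloidyParams()) -> set[str]:
    """Cells with at least ``good_cell_fraction`` of the 10th-ranked cell's reads.

    With fewer cells than ``good_cell_rank`` the rule degrades to keeping
    every cell (logged via warning).
    """
    totals = m.total_reads()
    if m.n_barcodes < p.good_cell_rank:
        warnings.warn(
            f"fewer than {p.good_cell_rank} cells; all treated as good quality"
        )
        return set(m.barcodes)
    ranked = np.sort(totals)[::-1]
    threshold = p.good_cell_fraction * ranked[p.good_cell_rank - 1]
    return {b for b, t in zip(m.barcodes, totals) if t >= threshold}


def normalize_counts(
    m: AmpliconMatrix,
    p: PloidyParams = PloidyParams(),
    good_cells: set[str] | None = None,
) -> pd.DataFrame:
    """Two-step normalized counts (cell mean, then good-cell amplicon median).

    Cells with zero total reads get NaN rows and are excluded from the
    medians. Returns a cell×amplicon DataFrame.
    """
    if m.n_barcodes == 0:
        raise ValidationError("empty matrix")
    if good_cells is None:
        good_cells = good_quality_cells(m, p)
    counts = m.counts.astype(float)
    row_means = counts.mean(axis=1)
    zero_rows = row_means == 0
    if zero_rows.any():
        warnings.warn(f"{int(zero_rows.sum())} cells with zero reads flagged NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        step1 = counts / row_means[:, None]
    step1[zero_rows] = np.nan
    good_mask = np.array([b in good_cells for b in m.barcodes]) & ~zero_rows
    if not good_mask.any():
        raise ValidationError("no good-quality cells with nonzero reads")
    col_medians = np.median(step1[good_mask], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        step2 = step1 / col_medians[None, :]
    step2[:, col_medians == 0] = np.nan
    return pd.DataFrame(step2, index=m.barcodes, columns=m.amplicons)


def compute_ploidy(norm: pd.DataFrame, baseline: set[str] | list[str]) -> PloidyMatrix:
    """Scale normalized counts to ploidy against a diploid baseline group.

    ``ploidy(cell, amp) = 2 × norm(cell, amp) / median over baseline``.
    Amplicons whose baseline median is zero are undefined (NaN) everywhere.
    """
    baseline = set(baseline)
    if not baseline:
        raise ValidationError("empty baseline")
    missing = baseline - set(norm.index)
    if missing:
        raise ValidationError(f"baseline cells not in matrix: {sorted(missing)[:5]}")
    base = norm.loc[sorted(baseline)]
    med = base.median(axis=0, skipna=True).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ploidy = 2.0 * norm.to_numpy() / med[None, :]
    undefined = (med == 0) | np.isnan(med)
    if undefined.any():
        warnings.warn(
            f"{int(undefined.sum())} amplicons with zero/NaN baseline median flagged"
        )
        ploidy[:, undefined] = np.nan
    return PloidyMatrix(
        cells=[str(c) for c in norm.index],
        amplicons=[str(a) for a in norm.columns],
        ploidy=ploidy,
        baseline_cells=baseline,
    )


def clone_median_ploidy(
    pm: PloidyMatrix,
    assignment: dict[str, str],
) -> pd.DataFrame:
    """Per-clone, per-amplicon median ploidy (clone×amplicon DataFrame).

    ``assignment`` maps cell → clone id; clones with no member cells in the
    matrix are omitted with a warning.
    """
    frame = pm.to_frame()
    clones = sorted(set(assignment.values()))
    rows = {}
    for clone in clones:
        members = [c for c, z in assignment.items() if z == clone and c in frame.index]
        if not members:
            warnings.warn(f"clone {clone!r} has no cells in the ploidy matrix; omitted")
            continue
        rows[clone] = frame.loc[members].median(axis=0, skipna=True)
    if not rows:
        raise ValidationError("no clone had any member cells")
    return pd.DataFrame(rows).T


def detect_homdel(medians: pd.DataFrame, p: PloidyParams = PloidyParams()) -> pd.DataFrame:
    """Boolean clone×amplicon homozygous-deletion calls (median < cutoff)."""
    return medians < p.homdel_ploidy_max
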