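"""Readers and writers for the named-matrix container and MAF-like tables.

The container is a plain HDF5 file holding the three count matrices and their
string index vectors, plus the amplicon panel table::

    /DP               (n_barcodes, n_variants)  int64
    /AD               (n_barcodes, n_variants)  int64
    /amplicon_counts  (n_barcodes_amp, n_amplicons) int64
    /barcodes, /variants, /amplicon_barcodes, /amplicons   UTF-8 strings
    /panel/{amplicon_id, chrom, start, end, gene}

It is a functional stand-in for vendor pipeline output, not a byte-level
clone of any proprietary schema. TSV export/import is provided for small
text fixtures.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    AmpliconMatrix,
    AmpliconPanel,
    BulkAnnotation,
    CellVariantData,
    FormatError,
    ValidationError,
    VariantId,
)

__all__ = [
    "write_container",
    "read_container",
    "read_bulk_annotations",
    "write_bulk_annotations",
    "write_tsv_matrices",
    "read_tsv_matrices",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_strings(grp: h5py.Group, name: str, values: list[str]) -> None:
    grp.create_dataset(name, data=np.array(values, dtype=object), dtype=_STR)


def _read_strings(f: h5py.File, name: str) -> list[str]:
    if name not in f:
        raise FormatError(f"container missing dataset {name!r}")
    return [v.decode() if isinstance(v, bytes) else str(v) for v in f[name][()]]


def write_container(
    data: CellVariantData,
    amplicon_matrix: AmpliconMatrix,
    panel: AmpliconPanel,
    path: str | Path,
) -> None:
    """Write validated matrices and the panel to an HDF5 container at ``path``."""
    if data.n_cells == 0:
        raise ValidationError("refusing to write a container with no cells")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("DP", data=data.DP)
        f.create_dataset("AD", data=data.AD)
        f.create_dataset("amplicon_counts", data=amplicon_matrix.counts)
        _write_strings(f, "barcodes", data.barcodes)
        _write_strings(f, "variants", [str(v) for v in data.variants])
        _write_strings(f, "amplicon_barcodes", amplicon_matrix.barcodes)
        _write_strings(f, "amplicons", amplicon_matrix.amplicons)
        pg = f.create_group("panel")
        _write_strings(pg, "amplicon_id", list(panel.table["amplicon_id"].astype(str)))
        _write_strings(pg, "chrom", list(panel.table["chrom"].astype(str)))
        pg.create_dataset("start", data=panel.table["start"].to_numpy(dtype=np.int64))
        pg.create_dataset("end", data=panel.table["end"].to_numpy(dtype=np.int64))
        _write_strings(pg, "gene", list(panel.table["gene"].astype(str)))


def read_container(path: str | Path) -> tuple[CellVariantData, AmpliconMatrix, AmpliconPanel]:
    """Read and validate a container written by :func:`write_container`.

    Raises :class:`FormatError` for missing datasets and
    :class:`ValidationError` for invariant violations (e.g. AD > DP, with the
    offending barcode and variant named).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in ("DP", "AD", "amplicon_counts", "panel"):
            if name not in f:
                raise FormatError(f"container missing dataset {name!r}")
        dp = f["DP"][()]
        ad = f["AD"][()]
        counts = f["amplicon_counts"][()]
        barcodes = _read_strings(f, "barcodes")
        variants = [VariantId.from_string(s) for s in _read_strings(f, "variants")]
        amp_barcodes = _read_strings(f, "amplicon_barcodes")
        amplicons = _read_strings(f, "amplicons")
        pg = f["panel"]
        panel = AmpliconPanel(
            pd.DataFrame(
                {
                    "amplicon_id": _read_strings(pg, "amplicon_id"),
                    "chrom": _read_strings(pg, "chrom"),
                    "start": pg["start"][()].astype(int),
                    "end": pg["end"][()].astype(int),
                    "gene": _read_strings(pg, "gene"),
                }
            )
        )
    data = CellVariantData(barcodes=barcodes, variants=variants, DP=dp, AD=ad)
    amp = AmpliconMatrix(barcodes=amp_barcodes, amplicons=amplicons, counts=counts)
    return data, amp, panel


_BULK_REQUIRED = ("chrom", "pos", "ref", "alt", "sample_id", "alt_reads", "total_reads", "is_normal")


def read_bulk_annotations(path: str | Path) -> list[BulkAnnotation]:
    """Read a MAF-like tab-separated table of bulk variant measurements.

    Required columns: chrom, pos, ref, alt, sample_id, alt_reads, total_reads,
    is_normal. An optional ``vaf`` column is validated against
    alt_reads/total_reads; if absent the VAF is derived from the counts.
    Unparsable rows are reported with their (1-based, header included) line
    number.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _BULK_REQUIRED if c not in table.columns]
    if missing:
        raise FormatError(f"bulk annotation table missing columns: {missing}")
    records: list[BulkAnnotation] = []
    for i, row in table.iterrows():
        lineno = int(i) + 2  # header is line 1
        try:
            variant = VariantId(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
            )
            alt_reads = int(row["alt_reads"])
            total_reads = int(row["total_reads"])
            if "vaf" in table.columns and row["vaf"] != "":
                vaf = float(row["vaf"])
            else:
                vaf = alt_reads / total_reads if total_reads > 0 else 0.0
            rec = BulkAnnotation(
                variant=variant,
                sample_id=str(row["sample_id"]),
                bulk_vaf=vaf,
                alt_reads=alt_reads,
                total_reads=total_reads,
                is_normal_sample=str(row["is_normal"]).strip().lower()
                in ("1", "true", "yes"),
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
        records.append(rec)
    return records


def write_bulk_annotations(records: list[BulkAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": [r.variant.chrom for r in records],
            "pos": [r.variant.pos for r in records],
            "ref": [r.variant.ref for r in records],
            "alt": [r.variant.alt for r in records],
            "sample_id": [r.sample_id for r in records],
            "vaf": [r.bulk_vaf for r in records],
            "alt_reads": [r.alt_reads for r in records],
            "total_reads": [r.total_reads for r in records],
            "is_normal": [int(r.is_normal_sample) for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def write_tsv_matrices(data: CellVariantData, amplicon_matrix: AmpliconMatrix, outdir: str | Path) -> None:
    """Export DP/AD/amplicon-count matrices as TSV files (small fixtures)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [str(v) for v in data.variants]
    pd.DataFrame(data.DP, index=data.barcodes, columns=cols).to_csv(outdir / "DP.tsv", sep="\t")
    pd.DataFrame(data.AD, index=data.barcodes, columns=cols).to_csv(outdir / "AD.tsv", sep="\t")
    amplicon_matrix.to_frame().to_csv(outdir / "amplicon_counts.tsv", sep="\t")


def read_tsv_matrices(outdir: str | Path) -> tuple[CellVariantData, AmpliconMatrix]:
    outdir = Path(outdir)
    dp = pd.read_csv(outdir / "DP.tsv", sep="\t", index_col=0)
    ad = pd.read_csv(outdir / "AD.tsv", sep="\t", index_col=0)
    amp = pd.read_csv(outdir / "amplicon_counts.tsv", sep="\t", index_col=0)
    data = CellVariantData(
        barcodes=[str(b) for b in dp.index],
        variants=[VariantId.from_string(c) for c in dp.columns],
        DP=dp.to_numpy(),
        AD=ad.to_numpy(),
    )
    matrix = AmpliconMatrix(
        barcodes=[str(b) for b in amp.index],
        amplicons=[str(c) for c in amp.columns],
        counts=amp.to_numpy(),
    )
    return data, matrix
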