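"""Readers and writers for narrowPeak, BED and gene-annotation tables.

All readers tolerate comment/header lines prefixed with ``#`` and blank
lines. Writers emit plain tab-separated text so outputs are diffable and
deterministic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .intervals import GENE_TABLE_COLUMNS, GenomicInterval, NarrowPeak, validate_gene_table

__all__ = [
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
]


def _data_lines(path: str | Path) -> Iterable[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield line.split("\t")


def _fmt(x: float) -> str:
    """Format a float the way MACS2 does: trim trailing zeros, keep precision."""
    s = f"{x:.5f}".rstrip("0").rstrip(".")
    return s if s else "0"


def read_narrowpeak(path: str | Path) -> list[NarrowPeak]:
    """Read a narrowPeak (BED6+4) file into NarrowPeak records."""
    peaks = []
    for fields in _data_lines(path):
        if len(fields) < 10:
            raise ValueError(f"{path}: narrowPeak line has {len(fields)} columns, need 10")
        chrom, start, end, name, score, strand = fields[:6]
        signal, p_score, q_score, summit = fields[6:10]
        peaks.append(
            NarrowPeak(
                interval=GenomicInterval(chrom, int(start), int(end), strand),
                name=name,
                score=int(score),
                signal_value=float(signal),
                p_score=float(p_score),
                q_score=float(q_score),
                summit_offset=int(summit),
            )
        )
    return peaks


def write_narrowpeak(peaks: Sequence[NarrowPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(p.score),
                        p.interval.strand,
                        _fmt(p.signal_value),
                        _fmt(p.p_score),
                        _fmt(p.q_score),
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 intervals (extra columns are ignored)."""
    out = []
    for fields in _data_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: BED line has fewer than 3 columns")
        strand = fields[5] if len(fields) >= 6 else "."
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2]), strand))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols += [names[i], "0", iv.strand]
            fh.write("\t".join(cols) + "\n")


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated gene-annotation table.

    Expected columns: gene_id, gene_name, chrom, tss, strand, biotype.
    A header line (with or without a leading ``#``) is detected and used.
    """
    df = pd.read_csv(path, sep="\t", comment=None)
    if df.columns[0].lstrip("#") == "gene_id":
        df = df.rename(columns={df.columns[0]: "gene_id"})
    elif "gene_id" not in df.columns:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=GENE_TABLE_COLUMNS)
    df["tss"] = df["tss"].astype(int)
    return validate_gene_table(df)


def write_gene_table(annotation: pd.DataFrame, path: str | Path) -> None:
    validate_gene_table(annotation)
    annotation.to_csv(path, sep="\t", index=False, columns=GENE_TABLE_COLUMNS)
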