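"""Interval arithmetic core shared by every analysis stage.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Peak summits are stored as offsets from ``start`` (narrowPeak column 10
convention); ``-1`` means the caller reported no summit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "NarrowPeak",
    "merge_intervals",
    "overlap_fraction",
    "nearest_tss_distance",
    "GENE_TABLE_COLUMNS",
    "validate_gene_table",
]

#: Required columns of a gene-annotation table (one row per transcript TSS).
GENE_TABLE_COLUMNS = ["gene_id", "gene_name", "chrom", "tss", "strand", "biotype"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval has empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class NarrowPeak:
    """A MACS2-style narrowPeak record (BED6+4).

    ``p_score`` and ``q_score`` are -log10 of the p-value and q-value
    respectively, so larger means more significant.
    """

    interval: GenomicInterval
    name: str = "."
    score: int = 0
    signal_value: float = 0.0
    p_score: float = 0.0
    q_score: float = 0.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.p_score < 0 or self.q_score < 0:
            raise ValueError(f"peak {self.name}: negative -log10 score")
        if self.summit_offset != -1 and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"interval of length {len(self.interval)}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int | None:
        """Absolute summit position, or None if the peak carries no summit."""
        if self.summit_offset == -1:
            return None
        return self.interval.start + self.summit_offset

    def point(self, mode: str = "summit") -> int:
        """Representative point: ``summit`` (fall back to centre) or ``centre``."""
        if mode == "summit" and self.summit is not None:
            return self.summit
        if mode not in ("summit", "centre"):
            raise ValueError(f"unknown point mode {mode!r}")
        return self.interval.centre

    def moved_to(self, interval: GenomicInterval) -> "NarrowPeak":
        offset = -1
        if self.summit is not None and interval.start <= self.summit < interval.end:
            offset = self.summit - interval.start
        return replace(self, interval=interval, summit_offset=offset)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or abutting intervals into a sorted, disjoint set.

    Abutting intervals (``a.end == b.start``) are merged, matching the
    bedtools-merge default. The union of covered bases is preserved.
    """
    items = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def overlap_fraction(
    subject: GenomicInterval, query_set: Sequence[GenomicInterval]
) -> float:
    """Fraction of ``subject`` bases covered by the union of ``query_set``.

    Query intervals are unioned first so overlapping queries are not
    double-counted. Returns a value in [0, 1].
    """
    covered = 0
    for q in merge_intervals(q for q in query_set if q.chrom == subject.chrom):
        covered += max(0, min(subject.end, q.end) - max(subject.start, q.start))
    return covered / len(subject)


def validate_gene_table(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check a gene-annotation table for the required columns and sane values."""
    missing = [c for c in GENE_TABLE_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    if (annotation["tss"] < 0).any():
        bad = annotation.loc[annotation["tss"] < 0, "gene_id"].iloc[0]
        raise ValueError(f"gene {bad}: negative TSS")
    return annotation


def nearest_tss_distance(
    points: Sequence[tuple[str, int]],
    annotation: pd.DataFrame,
    biotypes: Sequence[str] | None = ("protein_coding", "lincRNA"),
) -> list[tuple[float, str | None]]:
    """Signed distance from each point to the nearest TSS in ``annotation``.

    The sign is strand-aware: negative when the point lies 5' (upstream) of
    the TSS on the gene's strand, positive 3' (downstream). Only the
    magnitude is compared when choosing the nearest gene; ties are broken by
    smaller magnitude then lexicographic ``gene_id``. Points on chromosomes
    absent from the annotation get ``(nan, None)``.
    """
    validate_gene_table(annotation)
    ann = annotation
    if biotypes is not None:
        ann = ann[ann["biotype"].isin(biotypes)]

    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in ann.groupby("chrom"):
        by_chrom[chrom] = grp.sort_values(["tss", "gene_id"]).reset_index(drop=True)

    out: list[tuple[float, str | None]] = []
    for chrom, pos in points:
        grp = by_chrom.get(chrom)
        if grp is None or grp.empty:
            out.append((float("nan"), None))
            continue
        dist = np.abs(pos - grp["tss"].to_numpy())
        dmin = dist.min()
        ties = grp[dist == dmin]
        gene = ties.loc[ties["gene_id"].idxmin()] if len(ties) > 1 else ties.iloc[0]
        genomic = pos - int(gene["tss"])
        signed = -genomic if gene["strand"] == "-" else genomic
        out.append((float(signed), str(gene["gene_id"])))
    return out
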