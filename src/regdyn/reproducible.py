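"""Replicate/pseudoreplicate peak-retention and confidence filtering.

Peak callers emit five sets per mark and cell type: the two biological
replicates, the pooled replicates, and the two pooled pseudoreplicates
(random half-splits of the reads). A pooled peak is kept when it is
supported by both biological replicates, or rescued by both
pseudoreplicates — this lets a marginal call in one replicate survive if
the pooled evidence is strong. Support means the replicate peaks cover at
least a fraction ``min_overlap_frac`` of the pooled peak's own length
(default 0.20 for ATAC, 0.30 for histone marks).

The surviving peaks are then confidence-filtered on the caller's q-value:
-log10(q) strictly greater than 4.0 for ATAC (FDR < 1e-4) and 3.0 for
histone marks (FDR < 1e-3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .intervals import GenomicInterval, NarrowPeak, merge_intervals, overlap_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicatedPeakCalls",
    "DEFAULT_OVERLAP_FRAC",
    "DEFAULT_MIN_QSCORE",
    "retain_reproducible",
    "filter_by_qscore",
]

#: Default minimum overlap fraction of the pooled peak, by assay.
DEFAULT_OVERLAP_FRAC = {"ATAC": 0.20, "histone": 0.30}
#: Default minimum -log10(q) cutoff, by assay.
DEFAULT_MIN_QSCORE = {"ATAC": 4.0, "histone": 3.0}


@dataclass
class ReplicatedPeakCalls:
    """The five peak sets produced per (mark, cell type)."""

    pooled: list[NarrowPeak]
    rep1: list[NarrowPeak]
    rep2: list[NarrowPeak]
    pseudo1: list[NarrowPeak] = field(default_factory=list)
    pseudo2: list[NarrowPeak] = field(default_factory=list)
    assay: str = "ATAC"

    def __post_init__(self) -> None:
        if self.assay not in DEFAULT_OVERLAP_FRAC:
            raise ValueError(f"assay must be one of {sorted(DEFAULT_OVERLAP_FRAC)}")


def _support(
    pooled: list[NarrowPeak], supporting: list[NarrowPeak], f: float, reciprocal: bool
) -> list[bool]:
    """Per pooled peak: does the supporting set cover >= f of its length?"""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in supporting:
        by_chrom.setdefault(p.chrom, []).append(p.interval)
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}

    out = []
    for p in pooled:
        qs = merged.get(p.chrom, [])
        ok = overlap_fraction(p.interval, qs) >= f
        if ok and reciprocal:
            # also require some supporting peak to be covered >= f by the pooled peak
            ok = any(
                q.overlaps(p.interval)
                and overlap_fraction(q, [p.interval]) >= f
                for q in qs
            )
        out.append(ok)
    return out


def retain_reproducible(
    calls: ReplicatedPeakCalls,
    min_overlap_frac: float | None = None,
    reciprocal: bool = False,
) -> list[NarrowPeak]:
    """Retain pooled peaks supported by both replicates or both pseudoreplicates.

    A pooled peak P passes when ``overlap_fraction(P, rep1) >= f`` and the
    same for rep2, or the analogous pair of conditions on the
    pseudoreplicates. The overlap denominator is P's own length; multiple
    supporting peaks are unioned so coverage is never double-counted.
    Pooled records are returned unmodified, in input order.
    """
    f = min_overlap_frac
    if f is None:
        f = DEFAULT_OVERLAP_FRAC[calls.assay]
    if not 0 <= f <= 1:
        raise ValueError(f"min_overlap_frac must be in [0, 1], got {f}")
    if not calls.pooled:
        logger.warning("retain_reproducible: empty pooled peak set")
        return []

    r1 = _support(calls.pooled, calls.rep1, f, reciprocal)
    r2 = _support(calls.pooled, calls.rep2, f, reciprocal)
    s1 = _support(calls.pooled, calls.pseudo1, f, reciprocal)
    s2 = _support(calls.pooled, calls.pseudo2, f, reciprocal)

    kept = [
        p
        for p, a, b, c, d in zip(calls.pooled, r1, r2, s1, s2)
        if (a and b) or (c and d)
    ]
    logger.info(
        "retain_reproducible: kept %d/%d pooled peaks (f=%.2f, assay=%s)",
        len(kept), len(calls.pooled), f, calls.assay,
    )
    return kept


def filter_by_qscore(
    peaks: list[NarrowPeak], min_q_score: float | str = "ATAC"
) -> list[NarrowPeak]:
    """Keep peaks with -log10(q) strictly greater than the threshold.

    ``min_q_score`` may be a number or an assay name ('ATAC'/'histone') to
    use that assay's default. The boundary is excluded: FDR < 1e-4 means
    q_score > 4.0 exactly.
    """
    if isinstance(min_q_score, str):
        min_q_score = DEFAULT_MIN_QSCORE[min_q_score]
    return [p for p in peaks if p.q_score > min_q_score]
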