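"""Promoter/enhancer element sets, chromatin-state classification and
state-transition tracking along a cell-type trajectory.

Elements come in two kinds. Promoters are TSS +/- 1 kb windows over all
protein-coding and lincRNA transcripts, de-duplicated to non-redundant
intervals. Putative enhancers are distal open-chromatin summits (ATAC)
extended by +/- 500 bp, after removing any open region that touches a
promoter window; overlapping extended windows are merged.

Each element gets one chromatin state per cell type from a rule table over
histone-mark peak overlap: H3K4me1/H3K27ac/H3K27me3 for enhancers,
H3K4me3/H3K27ac/H3K27me3 for promoters. A mark counts as present when its
peaks cover at least 20% of the element length. The mark-combination ->
state mapping ships as a versioned YAML config (``data/state_rules.yaml``)
and can be overridden without code changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import GenomicInterval, NarrowPeak, merge_intervals, validate_gene_table

logger = logging.getLogger(__name__)

__all__ = [
    "Element",
    "ElementSet",
    "StateRules",
    "TransitionMatrix",
    "build_promoter_set",
    "build_enhancer_set",
    "classify_elements",
    "state_transitions",
    "state_fractions",
]

ENHANCER_STATES = ["active", "mixed", "primed", "poised", "repressed", "neutral"]
PROMOTER_STATES = ["active", "mixed", "poised", "repressed", "neutral"]


@dataclass(frozen=True)
class Element:
    element_id: str
    kind: str  # 'enhancer' or 'promoter'
    interval: GenomicInterval
    summit: int | None = None  # enhancers: representative ATAC summit
    genes: tuple[str, ...] = ()  # promoters: transcripts sharing this window

    @property
    def associated_gene(self) -> str | None:
        return self.genes[0] if self.genes else None


@dataclass
class ElementSet:
    """An ordered collection of elements with unique ids."""

    elements: list[Element]

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element ids")

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self):
        return iter(self.elements)

    def by_id(self) -> dict[str, Element]:
        return {e.element_id: e for e in self.elements}

    def intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.elements]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element_id": [e.element_id for e in self.elements],
                "kind": [e.kind for e in self.elements],
                "chrom": [e.interval.chrom for e in self.elements],
                "start": [e.interval.start for e in self.elements],
                "end": [e.interval.end for e in self.elements],
                "summit": [-1 if e.summit is None else e.summit for e in self.elements],
                "genes": [",".join(e.genes) for e in self.elements],
            }
        )


class StateRules:
    """Mark-combination -> state truth tables for both element kinds."""

    def __init__(self, config: Mapping):
        self._config = dict(config)
        for kind in ("enhancer", "promoter"):
            if kind not in config:
                raise ValueError(f"state rules missing section {kind!r}")
            marks = config[kind]["marks"]
            states = config[kind]["states"]
            missing = [
                key
                for key in ("".join(bits) for bits in _bitstrings(len(marks)))
                if key not in states
            ]
            if missing:
                raise ValueError(f"{kind} rules missing combinations: {missing}")
            if states["0" * len(marks)] != "neutral":
                raise ValueError(f"{kind}: the no-mark combination must map to neutral")

    @classmethod
    def default(cls) -> "StateRules":
        text = resources.files("regdyn").joinpath("data/state_rules.yaml").read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StateRules":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def marks(self, kind: str) -> list[str]:
        return list(self._config[kind]["marks"])

    def states(self, kind: str) -> list[str]:
        return ENHANCER_STATES if kind == "enhancer" else PROMOTER_STATES

    def state(self, kind: str, flags: Mapping[str, bool]) -> str:
        key = "".join("1" if flags[m] else "0" for m in self.marks(kind))
        return self._config[kind]["states"][key]


def _bitstrings(n: int):
    for i in range(2**n):
        yield format(i, f"0{n}b")


def build_promoter_set(
    annotation: pd.DataFrame, flank: int = 1000, biotypes: Sequence[str] | None = ("protein_coding", "lincRNA")
) -> ElementSet:
    """TSS +/- flank windows, collapsed to non-redundant intervals.

    Transcripts sharing a window are recorded together on one element.
    Windows extending past the chromosome start are clipped at 0.
    """
    validate_gene_table(annotation)
    ann = annotation
    if biotypes is not None:
        ann = ann[ann["biotype"].isin(biotypes)]

    groups: dict[tuple[str, int], list[str]] = {}
    for row in ann.itertuples():
        groups.setdefault((row.chrom, int(row.tss)), []).append(str(row.gene_id))

    n_clipped = 0
    elements = []
    for i, ((chrom, tss), genes) in enumerate(sorted(groups.items())):
        start = tss - flank
        if start < 0:
            n_clipped += 1
            start = 0
        iv = GenomicInterval(chrom, start, tss + flank)
        elements.append(
            Element(f"prom_{i:06d}", "promoter", iv, genes=tuple(sorted(set(genes))))
        )
    if n_clipped:
        logger.warning("build_promoter_set: clipped %d windows at position 0", n_clipped)
    return ElementSet(elements)


def build_enhancer_set(
    atac_peaks_by_celltype: Mapping[str, Sequence[NarrowPeak]],
    promoters: ElementSet,
    min_q_score: float = 4.0,
    flank: int = 500,
    missing_summit: str = "reject",
) -> ElementSet:
    """Construct the putative-enhancer set from per-cell-type ATAC peaks.

    Pipeline: q-score filter (-log10 q strictly > ``min_q_score``) -> merge
    peaks of all cell types into combined open regions -> pick each
    region's best summit (max q, ties to the leftmost coordinate) -> drop
    regions overlapping any promoter window by >= 1 bp -> extend summits
    by +/- ``flank`` -> merge overlapping windows, the merged element
    keeping its best constituent summit.
    """
    if missing_summit not in ("reject", "centre"):
        raise ValueError("missing_summit must be 'reject' or 'centre'")

    summits: list[tuple[str, int, float]] = []  # (chrom, position, q)
    kept_peaks: list[NarrowPeak] = []
    for ct, peaks in atac_peaks_by_celltype.items():
        for p in peaks:
            if p.q_score <= min_q_score:
                continue
            kept_peaks.append(p)
            if p.summit is None:
                if missing_summit == "reject":
                    raise ValueError(
                        f"peak {p.name} ({ct}) has no summit; "
                        "pass missing_summit='centre' to use the peak centre"
                    )
                summits.append((p.chrom, p.interval.centre, p.q_score))
            else:
                summits.append((p.chrom, p.summit, p.q_score))

    combined = merge_intervals(p.interval for p in kept_peaks)

    # index summits by chromosome for assignment to combined peaks
    by_chrom: dict[str, list[tuple[int, float]]] = {}
    for chrom, pos, q in summits:
        by_chrom.setdefault(chrom, []).append((pos, q))
    for lst in by_chrom.values():
        lst.sort()

    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for e in promoters:
        prom_by_chrom.setdefault(e.interval.chrom, []).append(e.interval)
    prom_merged = {c: merge_intervals(ivs) for c, ivs in prom_by_chrom.items()}

    def overlaps_promoter(iv: GenomicInterval) -> bool:
        return any(iv.overlaps(p) for p in prom_merged.get(iv.chrom, []))

    def best_summit(chrom: str, start: int, end: int) -> tuple[int, float]:
        cands = [(pos, q) for pos, q in by_chrom.get(chrom, []) if start <= pos < end]
        # max q; ties broken by leftmost position
        return max(cands, key=lambda t: (t[1], -t[0]))

    windows: list[tuple[GenomicInterval, int, float]] = []
    for iv in combined:
        if overlaps_promoter(iv):
            continue
        pos, q = best_summit(iv.chrom, iv.start, iv.end)
        windows.append(
            (GenomicInterval(iv.chrom, max(0, pos - flank), pos + flank), pos, q)
        )

    merged = merge_intervals(w[0] for w in windows)
    elements = []
    for i, iv in enumerate(merged):
        inside = [
            (pos, q)
            for w, pos, q in windows
            if w.chrom == iv.chrom and iv.start <= pos < iv.end
        ]
        pos, _ = max(inside, key=lambda t: (t[1], -t[0]))
        elements.append(Element(f"enh_{i:06d}", "enhancer", iv, summit=pos))
    return ElementSet(elements)


def _coverage(
    elements: Sequence[Element], peaks: Sequence[NarrowPeak]
) -> np.ndarray:
    """Fraction of each element covered by the union of the peak set."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p.interval)
    merged = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    arrs = {
        c: (np.array([m.start for m in ms]), np.array([m.end for m in ms]))
        for c, ms in merged.items()
    }
    out = np.zeros(len(elements))
    for i, e in enumerate(elements):
        if e.interval.chrom not in arrs:
            continue
        starts, ends = arrs[e.interval.chrom]
        lo = int(np.searchsorted(ends, e.interval.start, side="right"))
        hi = int(np.searchsorted(starts, e.interval.end, side="left"))
        if hi > lo:
            cov = np.minimum(ends[lo:hi], e.interval.end) - np.maximum(
                starts[lo:hi], e.interval.start
            )
            out[i] = cov.sum() / len(e.interval)
    return out


def classify_elements(
    elements: ElementSet,
    mark_peaks: Mapping[tuple[str, str], Sequence[NarrowPeak]],
    cell_types: Sequence[str] | None = None,
    min_overlap_frac: float = 0.2,
    rules: StateRules | None = None,
) -> pd.DataFrame:
    """Assign one chromatin state per element per cell type.

    ``mark_peaks`` maps (mark, cell_type) to a peak list. Returns a tidy
    frame with columns element_id, cell_type, state, and one boolean flag
    column per mark. The state is a pure function of the flags via the
    rule table; elements with no mark present are neutral.
    """
    if rules is None:
        rules = StateRules.default()
    if not elements.elements:
        return pd.DataFrame(columns=["element_id", "cell_type", "state"])
    kinds = {e.kind for e in elements}
    if len(kinds) != 1:
        raise ValueError("classify one element kind at a time")
    kind = kinds.pop()
    marks = rules.marks(kind)
    if cell_types is None:
        cell_types = sorted({ct for _, ct in mark_peaks})

    missing = [(m, ct) for ct in cell_types for m in marks if (m, ct) not in mark_peaks]
    if missing:
        raise ValueError(f"missing peak sets for (mark, cell_type): {missing}")

    frames = []
    for ct in cell_types:
        flags = {
            m: _coverage(elements.elements, mark_peaks[(m, ct)]) >= min_overlap_frac
            for m in marks
        }
        df = pd.DataFrame(
            {
                "element_id": [e.element_id for e in elements],
                "cell_type": ct,
                **{m: flags[m] for m in marks},
            }
        )
        df["state"] = [
            rules.state(kind, {m: bool(df[m].iat[i]) for m in marks})
            for i in range(len(df))
        ]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out[["element_id", "cell_type", "state", *marks]]


@dataclass
class TransitionMatrix:
    """Element counts flowing between states of two consecutive cell types."""

    source_cell_type: str
    target_cell_type: str
    counts: pd.DataFrame  # index: source state, columns: target state

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def _subset_ids(
    assignments: pd.DataFrame, subset: Iterable[str] | Callable[[str], bool] | None
) -> pd.DataFrame:
    if subset is None:
        return assignments
    if callable(subset):
        keep = assignments["element_id"].map(subset)
        return assignments[keep]
    ids = set(subset)
    return assignments[assignments["element_id"].isin(ids)]


def state_transitions(
    assignments: pd.DataFrame,
    ordered_cell_types: Sequence[str],
    subset: Iterable[str] | Callable[[str], bool] | None = None,
    states: Sequence[str] | None = None,
) -> list[TransitionMatrix]:
    """One state-by-state count matrix per consecutive cell-type pair.

    Every element in the (optionally subset) assignment table must carry a
    state in every listed cell type.
    """
    df = _subset_ids(assignments, subset)
    if states is None:
        states = [
            s
            for s in ENHANCER_STATES
            if s in set(df["state"])
        ] or sorted(set(df["state"]))
    wide = df.pivot(index="element_id", columns="cell_type", values="state")
    missing_ct = [ct for ct in ordered_cell_types if ct not in wide.columns]
    if missing_ct:
        raise ValueError(f"no assignments for cell types {missing_ct}")
    if wide[list(ordered_cell_types)].isna().any().any():
        bad = wide.index[wide[list(ordered_cell_types)].isna().any(axis=1)][:5]
        raise ValueError(f"elements missing a state in some cell type, e.g. {list(bad)}")

    out = []
    for a, b in zip(ordered_cell_types[:-1], ordered_cell_types[1:]):
        tab = pd.crosstab(wide[a], wide[b])
        tab = tab.reindex(index=states, columns=states, fill_value=0)
        tab.index.name, tab.columns.name = a, b
        out.append(TransitionMatrix(a, b, tab))
    return out


def state_fractions(assignments: pd.DataFrame, cell_type: str) -> pd.DataFrame:
    """Per-state element count and fraction in one cell type."""
    sub = assignments[assignments["cell_type"] == cell_type]
    counts = sub["state"].value_counts()
    df = pd.DataFrame({"count": counts, "fraction": counts / counts.sum()})
    df.index.name = "state"
    return df
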