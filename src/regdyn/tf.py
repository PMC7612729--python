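"""Combinatorial TF binding, regulatory potential and direct-target calling.

Three germline TFs (by default SOX17, PRDM1, TFAP2C) bind alone or
together: merging their peak sets gives a universe of bound regions, and
each region falls in one of the 7 non-empty cooperativity classes of the
trio. Pairwise co-binding significance is an upper-tail hypergeometric
test on the region universe.

A BETA-style regulatory potential scores each gene's likelihood of
regulation by a factor: a distance-decayed sum over the factor's peak
summits within 100 kb of the TSS, ``w(d) = exp(-(0.5 + 4 d/window))``.
Activator/repressor character is read off a one-tailed two-sample KS test
comparing regulatory potentials of knockout/overexpression-responsive
gene groups against unchanged genes. Direct targets combine the KO
response, peak proximity and chromatin context of the bound element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, NarrowPeak, merge_intervals, validate_gene_table

logger = logging.getLogger(__name__)

__all__ = [
    "TfPeakCollection",
    "beta_decay",
    "intersect_tf_peaks",
    "regulatory_potential",
    "predict_tf_function",
    "call_direct_targets",
    "region_set_enrichment",
    "hypergeom_overlap_pvalue",
]


@dataclass
class TfPeakCollection:
    tf_name: str
    peaks: list[NarrowPeak]
    context: str = "hPGCLC"


def beta_decay(delta: np.ndarray) -> np.ndarray:
    """Default regulatory-potential decay, delta = distance/window in [0,1]."""
    return np.exp(-(0.5 + 4.0 * np.asarray(delta, float)))


def _overlaps_any(iv: GenomicInterval, merged: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(m) for m in merged)


def hypergeom_overlap_pvalue(universe: int, n_a: int, n_b: int, k: int) -> float:
    """Upper-tail hypergeometric P[X >= k] of drawing k of A's regions in B."""
    return float(stats.hypergeom.sf(k - 1, universe, n_a, n_b))


def intersect_tf_peaks(
    collections: Sequence[TfPeakCollection],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition the merged peak universe into TF cooperativity classes.

    A merged region is "bound" by a TF when it overlaps >= 1 bp of that
    TF's peaks. Returns (classes, pairwise):

    - ``classes``: one row per non-empty TF subset, columns label (TF
      names joined with '+'), count, and region index lists; counts sum
      to the universe size.
    - ``pairwise``: per TF pair, bound counts, overlap and upper-tail
      hypergeometric p given the universe.
    """
    names = [c.tf_name for c in collections]
    if len(set(names)) != len(names):
        raise ValueError("duplicate TF names")
    for c in collections:
        if not c.peaks:
            logger.warning("intersect_tf_peaks: %s has no peaks", c.tf_name)

    universe = merge_intervals(p.interval for c in collections for p in c.peaks)
    merged_by_tf = {
        c.tf_name: merge_intervals(p.interval for p in c.peaks) for c in collections
    }
    bound = {
        name: np.array([_overlaps_any(iv, merged_by_tf[name]) for iv in universe])
        for name in names
    }

    rows = []
    for mask_bits in range(1, 2 ** len(names)):
        members = [names[i] for i in range(len(names)) if mask_bits >> i & 1]
        sel = np.ones(len(universe), dtype=bool)
        for i, name in enumerate(names):
            want = bool(mask_bits >> i & 1)
            sel &= bound[name] == want
        rows.append(
            {
                "label": "+".join(members),
                "tfs": tuple(members),
                "count": int(sel.sum()),
                "regions": [universe[i] for i in np.flatnonzero(sel)],
            }
        )
    classes = pd.DataFrame(rows)

    pair_rows = []
    n_univ = len(universe)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            k = int((bound[a] & bound[b]).sum())
            pair_rows.append(
                {
                    "tf_a": a,
                    "tf_b": b,
                    "n_a": int(bound[a].sum()),
                    "n_b": int(bound[b].sum()),
                    "overlap": k,
                    "p_value": hypergeom_overlap_pvalue(
                        n_univ, int(bound[a].sum()), int(bound[b].sum()), k
                    ),
                }
            )
    return classes, pd.DataFrame(pair_rows)


def regulatory_potential(
    peaks: TfPeakCollection,
    annotation: pd.DataFrame,
    window: int = 100_000,
    decay: Callable[[np.ndarray], np.ndarray] = beta_decay,
) -> pd.DataFrame:
    """Distance-decayed sum of a TF's peak summits within ``window`` of each TSS.

    score(g) = sum over peaks with |summit - TSS| <= window of
    decay(|d|/window). Additive over peaks; genes with no nearby peak
    score 0. Peaks without a summit use the peak centre.
    """
    validate_gene_table(annotation)
    summits: dict[str, np.ndarray] = {}
    for p in peaks.peaks:
        summits.setdefault(p.chrom, []).append(p.point("summit"))
    summits = {c: np.sort(np.asarray(v)) for c, v in summits.items()}

    scores = np.zeros(len(annotation))
    n_peaks = np.zeros(len(annotation), dtype=int)
    for i, row in enumerate(annotation.itertuples()):
        pos = summits.get(row.chrom)
        if pos is None:
            continue
        d = np.abs(pos - int(row.tss))
        near = d[d <= window]
        scores[i] = decay(near / window).sum()
        n_peaks[i] = near.size
    return pd.DataFrame(
        {
            "gene_id": annotation["gene_id"].to_numpy(),
            "tf_name": peaks.tf_name,
            "score": scores,
            "n_peaks": n_peaks,
        }
    )


def predict_tf_function(
    potentials: pd.DataFrame,
    response_groups: Mapping[str, Sequence[str]],
    min_group_size: int = 5,
) -> pd.DataFrame:
    """One-tailed KS comparison of regulatory potential per response group.

    ``response_groups`` maps {'up', 'down'} (and 'unchanged') to gene-id
    sets from an overexpression or knockout experiment. For each of
    up/down, the one-sided two-sample KS statistic tests whether the
    group's regulatory potentials are stochastically LARGER than the
    unchanged group's (i.e. the group's CDF lies below). A significant
    'up' group marks the TF as a direct activator; a significant 'down'
    group as a direct repressor. Groups smaller than ``min_group_size``
    are flagged unreliable.
    """
    if "unchanged" not in response_groups:
        raise ValueError("response_groups must include 'unchanged'")
    score = potentials.set_index("gene_id")["score"]
    unchanged = score.loc[score.index.intersection(response_groups["unchanged"])]
    rows = []
    for group in ("up", "down"):
        if group not in response_groups:
            continue
        vals = score.loc[score.index.intersection(response_groups[group])]
        if len(vals) == 0 or len(unchanged) == 0:
            raise ValueError(f"empty group for KS test: {group}")
        # alternative='less': CDF of first sample below the second,
        # i.e. the response group shifted toward HIGH potential
        res = stats.ks_2samp(vals, unchanged, alternative="less")
        rows.append(
            {
                "group": group,
                "n": len(vals),
                "ks_statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "unreliable": len(vals) < min_group_size,
            }
        )
    return pd.DataFrame(rows)


def call_direct_targets(
    class_peaks: Mapping[str, Sequence[NarrowPeak]],
    ko_tables: Mapping[str, pd.DataFrame],
    active_elements: Sequence[GenomicInterval],
    active_or_mixed_elements: Sequence[GenomicInterval],
    annotation: pd.DataFrame,
    window: int = 100_000,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Direct up/down target genes per TF cooperativity class.

    ``class_peaks`` maps a class label like 'SOX17+TFAP2C' to the peaks of
    that class; ``ko_tables`` maps each TF to a knockout differential
    table (columns gene_id, log2_fc, adj_p) of KO vs control.

    direct-up(g, class): g downregulated (log2FC < -1, adj p < 0.05) in
    the KO of EVERY member TF, a class peak summit within ``window`` of
    g's TSS, and at least one such peak overlapping an active-or-mixed
    element in the context cell type. direct-down mirrors with KO
    upregulation and NO nearby class peak overlapping an active element.
    """
    validate_gene_table(annotation)
    act = merge_intervals(active_elements) if len(active_elements) else []
    actmix = (
        merge_intervals(active_or_mixed_elements)
        if len(active_or_mixed_elements)
        else []
    )

    ko_down: dict[str, set[str]] = {}
    ko_up: dict[str, set[str]] = {}
    for tf, tab in ko_tables.items():
        sig = tab["adj_p"] < alpha
        ko_down[tf] = set(tab.loc[sig & (tab["log2_fc"] < -lfc_threshold), "gene_id"])
        ko_up[tf] = set(tab.loc[sig & (tab["log2_fc"] > lfc_threshold), "gene_id"])

    rows = []
    for label, peaks in class_peaks.items():
        tfs = label.split("+")
        missing = [tf for tf in tfs if tf not in ko_tables]
        if missing:
            logger.warning(
                "call_direct_targets: class %s skipped (no KO table for %s)",
                label, ",".join(missing),
            )
            continue
        down_all = set.intersection(*(ko_down[tf] for tf in tfs))
        up_all = set.intersection(*(ko_up[tf] for tf in tfs))

        by_chrom: dict[str, list[NarrowPeak]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)

        for g in annotation.itertuples():
            gid = str(g.gene_id)
            if gid not in down_all and gid not in up_all:
                continue
            near = [
                p
                for p in by_chrom.get(g.chrom, [])
                if abs(p.point("summit") - int(g.tss)) <= window
            ]
            if not near:
                continue
            touches_actmix = any(_overlaps_any(p.interval, actmix) for p in near)
            touches_act = any(_overlaps_any(p.interval, act) for p in near)
            if gid in down_all and touches_actmix:
                direction = "up"
            elif gid in up_all and not touches_act:
                direction = "down"
            else:
                continue
            tab_rows = {tf: ko_tables[tf].set_index("gene_id") for tf in tfs}
            rows.append(
                {
                    "gene_id": gid,
                    "class": label,
                    "direction": direction,
                    "n_peaks": len(near),
                    "min_abs_log2_fc": min(
                        abs(float(tab_rows[tf].loc[gid, "log2_fc"])) for tf in tfs
                    ),
                    "max_adj_p": max(
                        float(tab_rows[tf].loc[gid, "adj_p"]) for tf in tfs
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "class", "direction", "n_peaks", "min_abs_log2_fc", "max_adj_p"],
    )


def region_set_enrichment(
    query: Sequence[GenomicInterval],
    reference_sets: Mapping[str, Sequence[GenomicInterval]],
    universe: Sequence[GenomicInterval],
) -> pd.DataFrame:
    """Overlap fraction and hypergeometric enrichment of a query region set.

    ``universe`` must contain every query region (by exact coordinates).
    For each named reference set: fraction = #(query regions overlapping
    the reference by >= 1 bp) / #query, and the p-value is the upper-tail
    hypergeometric probability of that many overlapping regions given how
    many universe regions overlap the reference.
    """
    uni_keys = {(iv.chrom, iv.start, iv.end) for iv in universe}
    bad = [iv for iv in query if (iv.chrom, iv.start, iv.end) not in uni_keys]
    if bad:
        raise ValueError(
            f"universe is not a superset of the query ({len(bad)} regions missing, "
            f"e.g. {bad[0].chrom}:{bad[0].start}-{bad[0].end})"
        )
    rows = []
    for name, ref in reference_sets.items():
        merged = merge_intervals(ref)
        k_query = sum(_overlaps_any(iv, merged) for iv in query)
        k_universe = sum(_overlaps_any(iv, merged) for iv in universe)
        rows.append(
            {
                "reference": name,
                "fraction": k_query / len(query) if len(query) else 0.0,
                "overlap": int(k_query),
                "p_value": hypergeom_overlap_pvalue(
                    len(universe), k_universe, len(query), int(k_query)
                ),
            }
        )
    return pd.DataFrame(rows)
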