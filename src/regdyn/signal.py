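"""Mark-signal quantification and dynamics.

Fragment counts at elements or 1-kb bins are normalized with
library-depth size factors and log2(x+1)-transformed. Differential signal
between cell types uses a negative-binomial Wald test with a
method-of-moments dispersion pooled across the contrast — a documented,
pluggable approximation in the spirit of count-based differential tools,
not a reimplementation of any of them (no shrinkage). A region is
"dynamic" when |log2 fold change| > 1 and BH-adjusted p < 0.05.

Dynamically active/repressed elements are clustered by k-means on
per-element z-scores of the log-normalized signal across all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "make_analysis_bins",
    "count_fragments",
    "normalize",
    "differential_signal",
    "select_dynamic_elements",
    "cluster_dynamic",
    "mark_expression_roc",
    "CELL_TYPES",
]

#: Trajectory order of the in vitro differentiation model.
CELL_TYPES = ["hESC", "PreME", "ME", "DE", "hPGCLC", "hPGC"]


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    cell_type: str
    replicate: int
    mark: str  # ATAC, H3K4me1, H3K4me3, H3K27ac, H3K27me3 or RNA
    library_depth: float | None = None


@dataclass
class CountMatrix:
    """Raw fragment counts at regions across samples, plus normalized values.

    ``counts`` is regions x samples (integer); ``normalized`` holds
    log2(count / size_factor + 1) after :func:`normalize` and is None
    before.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta]
    regions: dict[str, GenomicInterval] | None = None
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("counts columns must match sample metadata order")
        keys = {(s.cell_type, s.replicate, s.mark) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(cell_type, replicate, mark) must be unique per sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def sample_ids(self, cell_type: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if cell_type is None or s.cell_type == cell_type
        ]

    def depths(self) -> pd.Series:
        vals = {
            s.sample_id: (
                s.library_depth
                if s.library_depth is not None
                else float(self.counts[s.sample_id].sum())
            )
            for s in self.samples
        }
        return pd.Series(vals)


def make_analysis_bins(
    combined_peaks: Sequence[GenomicInterval],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 1000,
) -> dict[str, GenomicInterval]:
    """Genome tiling bins that overlap at least one combined peak.

    Bins are ``[k*bin_size, (k+1)*bin_size)`` keyed by 'chrom:start-end'.
    """
    bins: dict[str, GenomicInterval] = {}
    for iv in combined_peaks:
        size = chrom_sizes[iv.chrom]
        for k in range(iv.start // bin_size, (iv.end - 1) // bin_size + 1):
            start = k * bin_size
            end = min((k + 1) * bin_size, size)
            if start >= end:
                continue
            bins[f"{iv.chrom}:{start}-{end}"] = GenomicInterval(iv.chrom, start, end)
    return dict(sorted(bins.items(), key=lambda kv: (kv[1].chrom, kv[1].start)))


def count_fragments(
    fragments_by_sample: Mapping[str, Sequence[GenomicInterval]],
    regions: Mapping[str, GenomicInterval],
    samples: list[SampleMeta] | None = None,
) -> CountMatrix:
    """Count fragments at regions; a fragment increments EVERY region it
    overlaps by >= 1 bp (featureCounts '-O' semantics)."""
    trees: dict[str, IntervalTree] = {}
    for rid, iv in regions.items():
        trees.setdefault(iv.chrom, IntervalTree())[iv.start : iv.end] = rid

    region_ids = list(regions)
    idx = {rid: i for i, rid in enumerate(region_ids)}
    mat = np.zeros((len(region_ids), len(fragments_by_sample)), dtype=int)
    for j, (sid, frags) in enumerate(fragments_by_sample.items()):
        for f in frags:
            tree = trees.get(f.chrom)
            if tree is None:
                continue
            for hit in tree[f.start : f.end]:
                mat[idx[hit.data], j] += 1

    if samples is None:
        samples = [
            SampleMeta(sid, cell_type=sid, replicate=1, mark="NA")
            for sid in fragments_by_sample
        ]
    counts = pd.DataFrame(mat, index=region_ids, columns=list(fragments_by_sample))
    return CountMatrix(counts=counts, samples=samples, regions=dict(regions))


def _size_factors(cm: CountMatrix, method: str) -> pd.Series:
    if method == "library_depth":
        depths = cm.depths()
        if (depths <= 0).any():
            bad = depths.index[depths <= 0][0]
            raise ValueError(f"sample {bad}: non-positive library depth")
        return depths / stats.gmean(depths)
    if method == "median_of_ratios":
        logc = np.log(cm.counts.replace(0, np.nan))
        logmeans = logc.mean(axis=1)
        ok = logmeans.notna()
        if not ok.any():
            raise ValueError("median-of-ratios: no region with all-positive counts")
        ratios = logc.loc[ok].sub(logmeans[ok], axis=0)
        sf = np.exp(ratios.median(axis=0))
        return sf
    raise ValueError(f"unknown size-factor method {method!r}")


def normalize(cm: CountMatrix, method: str = "library_depth") -> CountMatrix:
    """Return a new CountMatrix with size factors and log2-normalized values.

    Default size factor is relative library depth: s_j = depth_j /
    geometric-mean(depths). ``normalized = log2(count / s_j + 1)``, which
    preserves within-sample rank order of counts.
    """
    sf = _size_factors(cm, method)
    norm = np.log2(cm.counts.div(sf, axis=1) + 1.0)
    return replace(cm, size_factors=sf, normalized=norm)


def differential_signal(
    cm: CountMatrix,
    contrast: tuple[str, str],
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Per-region differential signal between two cell types (B vs A).

    Negative-binomial Wald test: counts are put on a common scale with the
    size factors; the per-region NB dispersion is estimated by method of
    moments from the within-group residual variance pooled across the
    contrast, then moderated toward the median dispersion across regions
    with ``prior_df`` prior degrees of freedom (at two replicates per
    group the raw estimate has only 2 df and sharing information across
    regions is what makes the test usable). The Wald statistic for the
    log2 fold change (delta-method standard error) is referred to a t
    distribution with (n_samples - 2 + prior_df) degrees of freedom.
    p-values are BH-adjusted across regions. ``dynamic`` flags
    |log2FC| > lfc_threshold and adj_p < alpha.
    """
    a, b = contrast
    cols_a, cols_b = cm.sample_ids(a), cm.sample_ids(b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition, got {len(cols_a)} ({a}) "
            f"and {len(cols_b)} ({b})"
        )
    sf = cm.size_factors if cm.size_factors is not None else _size_factors(cm, "library_depth")
    q = cm.counts.div(sf, axis=1)
    qa, qb = q[cols_a].to_numpy(float), q[cols_b].to_numpy(float)
    sa, sb = sf[cols_a].to_numpy(), sf[cols_b].to_numpy()
    na, nb = qa.shape[1], qb.shape[1]
    df_resid = na + nb - 2

    ma, mb = qa.mean(axis=1), qb.mean(axis=1)
    rss = ((qa - ma[:, None]) ** 2).sum(axis=1) + ((qb - mb[:, None]) ** 2).sum(axis=1)
    v = rss / df_resid
    m_all = (qa.sum(axis=1) + qb.sum(axis=1)) / (na + nb)
    inv_s_mean = (np.sum(1.0 / sa) + np.sum(1.0 / sb)) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp_mom = (v - m_all * inv_s_mean) / np.square(m_all)
    disp_mom = np.where(np.isfinite(disp_mom), np.maximum(disp_mom, 0.0), 0.0)
    central = float(np.median(disp_mom[disp_mom > 0])) if (disp_mom > 0).any() else 0.0
    disp = (df_resid * disp_mom + prior_df * central) / (df_resid + prior_df)

    # Var of a group's normalized mean: (1/n^2) sum_j (m/s_j + disp m^2)
    var_ma = (ma[:, None] / sa[None, :] + disp[:, None] * ma[:, None] ** 2).sum(axis=1) / na**2
    var_mb = (mb[:, None] / sb[None, :] + disp[:, None] * mb[:, None] ** 2).sum(axis=1) / nb**2

    c = pseudocount
    lfc = np.log2(mb + c) - np.log2(ma + c)
    ln2 = np.log(2.0)
    se2 = (var_ma / np.square(ma + c) + var_mb / np.square(mb + c)) / ln2**2
    se = np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(w), df=df_resid + prior_df)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "region_id": cm.counts.index,
            "log2_fc": lfc,
            "p_value": p,
            "adj_p_value": adj,
            "contrast_a": a,
            "contrast_b": b,
        }
    )
    out["dynamic"] = (np.abs(out["log2_fc"]) > lfc_threshold) & (
        out["adj_p_value"] < alpha
    )
    return out


def select_dynamic_elements(
    assignments: pd.DataFrame,
    diffs: Mapping[tuple[str, str], pd.DataFrame],
    state_predicate: Sequence[str] = ("active",),
    exclude_constitutive: bool = True,
) -> set[str]:
    """Elements in a target state somewhere, with differential signal somewhere.

    Selects elements whose state matches ``state_predicate`` in at least
    one cell type AND that are flagged dynamic in at least one of the
    supplied contrasts. When ``exclude_constitutive`` (the active-enhancer
    variant), elements matching the predicate in every cell type are
    removed.
    """
    pred = set(state_predicate)
    wide = assignments.pivot(index="element_id", columns="cell_type", values="state")
    matches = wide.isin(pred)
    in_some = matches.any(axis=1)
    keep = set(wide.index[in_some])
    if exclude_constitutive:
        keep -= set(wide.index[matches.all(axis=1)])

    dynamic: set[str] = set()
    for d in diffs.values():
        dynamic |= set(d.loc[d["dynamic"], "region_id"])
    return keep & dynamic


def cluster_dynamic(
    normalized: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 25,
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means over per-element z-scores of the normalized signal.

    Rows are elements, columns samples. Each row is z-scored across all
    samples (constant rows become all-zero). Returns (labels in 1..k
    indexed by element, cluster-mean z-profiles). Deterministic given the
    seed: k-means++ with ``n_init`` restarts.
    """
    if k > len(normalized):
        raise ValueError(f"k={k} exceeds number of elements {len(normalized)}")
    x = normalized.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (x - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(z) + 1
    out = pd.Series(labels, index=normalized.index, name="cluster")
    profiles = pd.DataFrame(km.cluster_centers_, columns=normalized.columns)
    profiles.index = pd.RangeIndex(1, k + 1, name="cluster")
    return out, profiles


def mark_expression_roc(
    states: pd.Series,
    signal: pd.Series,
    expression: pd.Series,
    top_n: int = 1000,
    tail: str = "top",
) -> float:
    """AUC of a mark's promoter signal for separating extreme-expression genes.

    Neutral promoters (no chromatin peak) are excluded. Positives are the
    promoters of the ``top_n`` highest- ('top') or lowest- ('bottom')
    expressed genes among the non-neutral set; all remaining non-neutral
    promoters are negatives. The AUC is the Mann-Whitney U statistic
    scaled to [0, 1] (midranks on ties), so it is invariant under strictly
    monotone transforms of the signal.
    """
    if tail not in ("top", "bottom"):
        raise ValueError("tail must be 'top' or 'bottom'")
    keep = states.index[states != "neutral"]
    keep = [i for i in keep if i in signal.index and i in expression.index]
    if len(keep) <= top_n:
        logger.warning(
            "mark_expression_roc: only %d non-neutral promoters for top_n=%d",
            len(keep), top_n,
        )
    expr = expression.loc[keep].sort_values(
        ascending=(tail == "bottom"), kind="mergesort"
    )
    pos = list(expr.index[:top_n])
    neg = [i for i in keep if i not in set(pos)]
    if not pos or not neg:
        raise ValueError("need both positive and negative promoters")
    u = stats.mannwhitneyu(signal.loc[pos], signal.loc[neg], alternative="two-sided")
    return float(u.statistic / (len(pos) * len(neg)))
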