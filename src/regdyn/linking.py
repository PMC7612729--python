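"""Enhancer-to-gene assignment and correlation-based link confidence.

Each enhancer is first assigned to the nearest gene by summit-to-TSS
distance (within 100 kb). The candidate pair is then scored by Kendall's
tau-b between the enhancer's H3K27ac signal and the gene's expression
across the 12 samples (6 cell types x 2 replicates). Because genomic
proximity alone yields many spurious pairs, significance comes from an
empirical same-chromosome null: the enhancer's tau against every other
(expressed) gene on its chromosome, with the empirical p the fraction of
null taus at least as large as the observed one. High-confidence links
require tau >= 0.3 and empirical p <= 0.05 (both boundaries inclusive).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .elements import ElementSet
from .intervals import validate_gene_table

logger = logging.getLogger(__name__)

__all__ = [
    "kendall_tau",
    "kendall_tau_matrix",
    "assign_nearest_gene",
    "empirical_link_pvalue",
    "link_enhancers_to_genes",
    "call_high_confidence",
]


def _pair_signs(x: np.ndarray) -> np.ndarray:
    """Sign of (x_j - x_i) over all pairs i<j, shape (..., n*(n-1)/2)."""
    n = x.shape[-1]
    i, j = np.triu_indices(n, k=1)
    return np.sign(x[..., j] - x[..., i])


def _tie_term(x: np.ndarray) -> np.ndarray:
    """Sum over tied groups of t*(t-1)/2, vectorized over rows."""
    s = _pair_signs(x)
    return (s == 0).sum(axis=-1)


def kendall_tau_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Kendall's tau-b of vector ``x`` against each row of matrix ``y``.

    Direct all-pairs concordance counting with tie correction — exact for
    the short (n = 12) profiles used here. Rows where either vector has
    zero variance yield NaN.
    """
    x = np.asarray(x, float)
    y = np.atleast_2d(np.asarray(y, float))
    sx = _pair_signs(x)
    sy = _pair_signs(y)
    n = x.shape[-1]
    n0 = n * (n - 1) // 2
    cd = sy @ sx  # concordant minus discordant per row
    n1 = (sx == 0).sum()
    n2 = (sy == 0).sum(axis=-1)
    denom2 = (n0 - n1) * (n0 - n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(denom2 > 0, cd / np.sqrt(np.maximum(denom2, 1)), np.nan)
    return tau


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Kendall rank correlation (tau-b) of two vectors.

    Returns NaN when either vector is constant (correlation undefined).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return float(kendall_tau_matrix(x, np.asarray([y]))[0])


def assign_nearest_gene(
    enhancers: ElementSet,
    annotation: pd.DataFrame,
    max_distance: int = 100_000,
    biotypes: Sequence[str] | None = ("protein_coding", "lincRNA"),
) -> pd.DataFrame:
    """Nearest gene per enhancer by summit-to-TSS distance, within a window.

    Returns columns enhancer_id, gene_id, distance (bp, unsigned). An
    enhancer with no TSS strictly closer than ``max_distance`` is left out
    (unassigned). Ties go to the smaller distance then lexicographically
    smaller gene_id.
    """
    validate_gene_table(annotation)
    ann = annotation
    if biotypes is not None:
        ann = ann[ann["biotype"].isin(biotypes)]
    rows = []
    for chrom, grp in ann.groupby("chrom"):
        tss = grp["tss"].to_numpy()
        gids = grp["gene_id"].to_numpy()
        order = np.lexsort((gids, tss))
        tss, gids = tss[order], gids[order]
        for e in enhancers:
            if e.interval.chrom != chrom:
                continue
            point = e.summit if e.summit is not None else e.interval.centre
            d = np.abs(point - tss)
            dmin = d.min()
            if dmin >= max_distance:
                continue
            cand = gids[d == dmin]
            rows.append((e.element_id, str(cand.min()), int(dmin)))
    return pd.DataFrame(rows, columns=["enhancer_id", "gene_id", "distance"])


def empirical_link_pvalue(
    enhancer_signal: Sequence[float],
    chrom_expression: pd.DataFrame,
    observed_tau: float,
    exclude_gene: str | None = None,
    add_one: bool = False,
) -> float:
    """Empirical p of an observed tau against the same-chromosome null.

    The null is the enhancer's tau with every gene in
    ``chrom_expression`` (genes x samples), excluding ``exclude_gene``
    (the focal gene) if given. p = #(null tau >= observed) / N, or
    (k+1)/(N+1) with ``add_one``.
    """
    genes = chrom_expression.index
    if exclude_gene is not None:
        genes = genes[genes != exclude_gene]
    if len(genes) == 0:
        raise ValueError("empty null gene set")
    null = kendall_tau_matrix(
        np.asarray(enhancer_signal, float), chrom_expression.loc[genes].to_numpy()
    )
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("all null taus undefined (constant expression rows)")
    k = int((null >= observed_tau).sum())
    if add_one:
        return (k + 1) / (null.size + 1)
    return k / null.size


def link_enhancers_to_genes(
    enhancers: ElementSet,
    enhancer_signal: pd.DataFrame,
    expression: pd.DataFrame,
    annotation: pd.DataFrame,
    max_distance: int = 100_000,
    tau_min: float = 0.3,
    p_max: float = 0.05,
    min_expression: float = 0.0,
    exclude_focal: bool = True,
    add_one: bool = False,
) -> pd.DataFrame:
    """Full linking pipeline: nearest gene, tau, empirical p, confidence call.

    ``enhancer_signal`` is enhancers x samples (log-normalized H3K27ac),
    ``expression`` genes x samples on matching columns. Genes whose mean
    expression is below ``min_expression`` are dropped from both the
    candidate pairs and the null. Pairs with undefined tau (constant
    signal or expression) are dropped with a warning.
    """
    if list(enhancer_signal.columns) != list(expression.columns):
        raise ValueError("enhancer signal and expression must share sample columns")
    expressed = expression[expression.mean(axis=1) >= min_expression]
    ann = annotation[annotation["gene_id"].isin(expressed.index)]
    pairs = assign_nearest_gene(enhancers, ann, max_distance=max_distance)

    chrom_of = dict(zip(ann["gene_id"], ann["chrom"]))
    expr_by_chrom = {
        chrom: expressed.loc[[g for g in ann.loc[ann["chrom"] == chrom, "gene_id"]]]
        for chrom in ann["chrom"].unique()
    }

    rows = []
    n_dropped = 0
    for pair in pairs.itertuples():
        x = enhancer_signal.loc[pair.enhancer_id].to_numpy(float)
        y = expressed.loc[pair.gene_id].to_numpy(float)
        tau = kendall_tau(x, y)
        if np.isnan(tau):
            n_dropped += 1
            continue
        p = empirical_link_pvalue(
            x,
            expr_by_chrom[chrom_of[pair.gene_id]],
            tau,
            exclude_gene=pair.gene_id if exclude_focal else None,
            add_one=add_one,
        )
        rows.append((pair.enhancer_id, pair.gene_id, pair.distance, tau, p))
    if n_dropped:
        logger.warning("link: dropped %d pairs with undefined tau", n_dropped)
    table = pd.DataFrame(
        rows, columns=["enhancer_id", "gene_id", "distance", "tau", "empirical_p"]
    )
    return call_high_confidence(table, tau_min=tau_min, p_max=p_max)


def call_high_confidence(
    pairs: pd.DataFrame, tau_min: float = 0.3, p_max: float = 0.05
) -> pd.DataFrame:
    """Flag pairs with tau >= tau_min and empirical p <= p_max (inclusive)."""
    out = pairs.copy()
    out["high_confidence"] = (out["tau"] >= tau_min) & (out["empirical_p"] <= p_max)
    return out
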