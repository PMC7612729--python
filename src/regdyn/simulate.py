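"""Synthetic in-silico study with planted ground truth.

Generates everything the analysis stages consume — gene annotation, peak
sets with replicate/pseudoreplicate structure, negative-binomial count
matrices, expression, TF ChIP peaks and knockout tables — from a single
seeded configuration, so every stage of the pipeline is testable without
any sequencing data.

What the generator emulates, and how:

* The study design: 6 cell types along a differentiation trajectory
  (hESC, PreME, ME, DE, hPGCLC, hPGC), 2 replicates each.
* Genes are laid out with a minimum TSS spacing; each gene anchors up to
  8 enhancer "slots" placed 2.5-11 kb from its TSS, far enough from all
  promoter windows to be distal and close enough that the anchor gene is
  always the nearest.
* Each enhancer carries a state program per cell type. Half follow one of
  9 activity archetypes (cell-type-specific, ramps, germline) and are
  "active" where the archetype activity is high; some are constitutively
  active; the rest draw static primed/poised/repressed/mixed/neutral
  states. Mark peaks are emitted from the state via the same truth table
  the classifier uses, so the noise-free channel is exactly invertible.
* Replicate peak sets drop peaks at a configurable rate and jitter peak
  boundaries; the pooled set is the noise-free planted set, and
  pseudoreplicates are independent noisy copies.
* H3K27ac counts at enhancers are negative binomial around a latent
  activity (state mean x archetype activity x a shared log-normal
  cell-type jitter). Genes with a planted link express that same latent
  plus their own NB noise, which is what makes the link discoverable by
  rank correlation; unlinked genes have flat expression.
* Three TFs bind in 7 cooperativity classes. Planted direct-up targets
  get class peaks on an hPGCLC-active enhancer; direct-down targets get
  class peaks in open desert; knockout tables carry the planted fold
  changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .elements import Element, ElementSet, build_promoter_set
from .intervals import GenomicInterval, NarrowPeak
from .reproducible import ReplicatedPeakCalls
from .signal import CELL_TYPES, CountMatrix, SampleMeta

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_study",
    "simulate_null_counts",
    "emit_fragments",
    "ARCHETYPES",
]

#: Activity profiles over the 6 cell types defining the dynamic archetypes:
#: one per cell type, two ramps, and a germline (hPGCLC+hPGC) profile.
ARCHETYPES: dict[int, np.ndarray] = {
    **{i + 1: np.eye(6)[i] for i in range(6)},
    7: np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0]),
    8: np.array([1.0, 0.8, 0.6, 0.4, 0.2, 0.0]),
    9: np.array([0.0, 0.0, 0.0, 0.0, 1.0, 1.0]),
}

#: Canonical mark combination emitted for each planted state (the unique
#: combination the default truth table maps back to that state).
ENHANCER_STATE_FLAGS = {
    "active": ("H3K4me1", "H3K27ac"),
    "mixed": ("H3K4me1", "H3K27ac", "H3K27me3"),
    "primed": ("H3K4me1",),
    "poised": ("H3K4me1", "H3K27me3"),
    "repressed": ("H3K27me3",),
    "neutral": (),
}
PROMOTER_STATE_FLAGS = {
    "active": ("H3K4me3", "H3K27ac"),
    "mixed": ("H3K4me3", "H3K27ac", "H3K27me3"),
    "poised": ("H3K4me3", "H3K27me3"),
    "repressed": ("H3K27me3",),
    "neutral": (),
}

DEFAULT_MEAN_BY_STATE = {
    "H3K27ac": {
        "active": 200.0, "mixed": 120.0, "primed": 30.0,
        "poised": 15.0, "repressed": 8.0, "neutral": 5.0,
    },
    "H3K27me3": {
        "active": 5.0, "mixed": 100.0, "poised": 120.0,
        "repressed": 150.0, "neutral": 4.0,
    },
}


@dataclass
class SimulationConfig:
    """Study conditions of the default in-silico experiment.

    The default scale (2 chromosomes x 10 Mb, 300 genes, 2,000 enhancers)
    runs the whole pipeline in minutes on one CPU while keeping enough
    elements per state and per archetype for stable statistics.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 10_000_000
    n_genes: int = 300
    n_enhancers: int = 2000
    cell_types: tuple[str, ...] = tuple(CELL_TYPES)
    replicates: int = 2
    min_gene_spacing: int = 30_000
    gene_margin: int = 200_000
    enhancer_flank: int = 500
    # program mixture
    p_archetype: float = 0.5
    p_constitutive: float = 0.1
    # linking
    link_fraction: float = 0.5  # of genes whose slot-0 enhancer is an archetype
    link_strength: float = 1.0
    expression_base: float = 20.0
    unlinked_expression_mean: float = 100.0
    # counts
    nb_dispersion: float = 0.05
    activity_jitter: float = 0.6  # sd of the shared log-normal cell-type jitter
    mean_by_state: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MEAN_BY_STATE.items()}
    )
    # replicate peak noise
    peak_drop_rate: float = 0.05
    peak_shift_sd: float = 30.0
    # TF experiment
    tf_names: tuple[str, ...] = ("SOX17", "PRDM1", "TFAP2C")
    targets_per_class: int = 3  # per direction
    background_peaks_per_class: int = 30
    ko_effect: float = 1.8
    ko_effect_sd: float = 0.3

    def validate(self) -> None:
        for name, p in [
            ("p_archetype", self.p_archetype),
            ("p_constitutive", self.p_constitutive),
            ("link_fraction", self.link_fraction),
            ("peak_drop_rate", self.peak_drop_rate),
        ]:
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.p_archetype + self.p_constitutive > 1:
            raise ValueError("program probabilities exceed 1")
        for mark, means in self.mean_by_state.items():
            if any(m < 0 for m in means.values()):
                raise ValueError(f"negative mean for {mark}")


@dataclass
class GroundTruth:
    """The planted structure every analysis stage should recover."""

    enhancer_states: pd.DataFrame  # element_id, cell_type, state
    promoter_states: pd.DataFrame  # gene_id keyed via promoter element ids
    links: pd.DataFrame  # enhancer_id, gene_id
    archetype: pd.Series  # enhancer_id -> archetype (0 = not dynamic)
    tf_targets: pd.DataFrame  # gene_id, class, direction


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: pd.DataFrame
    enhancers: ElementSet
    promoters: ElementSet
    truth: GroundTruth
    peak_calls: dict[tuple[str, str], ReplicatedPeakCalls]
    reproducible_peaks: dict[tuple[str, str], list[NarrowPeak]]
    atac_by_celltype: dict[str, list[NarrowPeak]]
    enhancer_counts: dict[str, CountMatrix]
    promoter_counts: dict[str, CountMatrix]
    expression: pd.DataFrame
    rna_samples: list[SampleMeta]
    tf_peaks: dict[str, list[NarrowPeak]]
    ko_tables: dict[str, pd.DataFrame]
    enhancer_latent: pd.DataFrame | None = None  # elements x cell types


def simulate_annotation(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes uniformly with a minimum TSS spacing."""
    config.validate()
    per_chrom = math.ceil(config.n_genes / config.n_chromosomes)
    usable = config.chrom_length - 2 * config.gene_margin
    if per_chrom * config.min_gene_spacing > usable:
        raise ValueError(
            f"cannot place {per_chrom} genes with spacing {config.min_gene_spacing} "
            f"in {usable} bp"
        )
    rows = []
    idx = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_here = min(per_chrom, config.n_genes - idx)
        jitter_room = max(config.min_gene_spacing // 4, 1)
        pos = config.gene_margin
        for _ in range(n_here):
            tss = pos + int(rng.integers(0, jitter_room))
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "protein_coding" if rng.random() < 0.9 else "lincRNA"
            rows.append(
                {
                    "gene_id": f"g{idx:04d}",
                    "gene_name": f"GENE{idx:04d}",
                    "chrom": chrom,
                    "tss": tss,
                    "strand": strand,
                    "biotype": biotype,
                }
            )
            pos += config.min_gene_spacing
            idx += 1
    return pd.DataFrame(rows)


def _place_enhancers(
    config: SimulationConfig, annotation: pd.DataFrame, rng: np.random.Generator
) -> tuple[ElementSet, pd.DataFrame]:
    """Assign enhancers to gene-anchored slots and build the element set.

    Slot k of a gene sits on alternating sides of the TSS at ring
    distances 2.5, 5, 7.5, 10 kb (plus <=500 bp jitter), so windows never
    overlap each other, never touch a promoter, and the anchor gene is
    always the nearest TSS. Element ids follow (chrom, start) order, the
    same naming the enhancer-construction stage produces.
    """
    n_slots = math.ceil(config.n_enhancers / config.n_genes)
    if n_slots > 8:
        raise ValueError("too many enhancers per gene (max 8 slots)")
    recs = []
    genes = annotation.reset_index(drop=True)
    for i in range(config.n_enhancers):
        gi = i % len(genes)
        slot = i // len(genes)
        g = genes.iloc[gi]
        side = 1 if slot % 2 == 0 else -1
        ring = slot // 2
        offset = 2500 + ring * 2500 + int(rng.integers(0, 500))
        summit = int(g["tss"]) + side * offset
        recs.append(
            {
                "chrom": g["chrom"],
                "summit": summit,
                "gene_id": g["gene_id"],
                "slot": slot,
            }
        )
    df = pd.DataFrame(recs).sort_values(["chrom", "summit"], kind="mergesort")
    df["element_id"] = [f"enh_{i:06d}" for i in range(len(df))]
    elements = [
        Element(
            r.element_id,
            "enhancer",
            GenomicInterval(
                r.chrom, r.summit - config.enhancer_flank, r.summit + config.enhancer_flank
            ),
            summit=r.summit,
        )
        for r in df.itertuples()
    ]
    return ElementSet(elements), df.reset_index(drop=True)


def _pick_targets(
    config: SimulationConfig, slots: pd.DataFrame, n_genes: int
) -> pd.DataFrame:
    """Choose planted TF target genes, spaced >= 4 gene slots apart so the
    class peaks of different targets never fall within 100 kb of each other."""
    classes = []
    names = config.tf_names
    for mask in range(1, 2 ** len(names)):
        classes.append("+".join(n for i, n in enumerate(names) if mask >> i & 1))
    need = len(classes) * config.targets_per_class * 2
    cand = list(range(0, n_genes, 4))
    if len(cand) < need:
        raise ValueError(
            f"not enough genes for {need} TF targets (have {len(cand)} spaced "
            "slots); lower targets_per_class or raise n_genes"
        )
    rows = []
    k = 0
    for direction in ("up", "down"):
        for label in classes:
            for _ in range(config.targets_per_class):
                rows.append(
                    {"gene_id": f"g{cand[k]:04d}", "class": label, "direction": direction}
                )
                k += 1
    return pd.DataFrame(rows)


def _assign_programs(
    config: SimulationConfig,
    slots: pd.DataFrame,
    tf_targets: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-enhancer archetype (0 = none) and per-enhancer state table."""
    up_target_genes = set(tf_targets.loc[tf_targets["direction"] == "up", "gene_id"])
    background_states = ["primed", "poised", "repressed", "neutral", "mixed"]
    background_p = [0.3, 0.15, 0.15, 0.3, 0.1]

    archetype = {}
    state_rows = []
    for r in slots.itertuples():
        if r.slot == 0 and r.gene_id in up_target_genes:
            kind = "constitutive"  # guarantees an hPGCLC-active element
        else:
            u = rng.random()
            if u < config.p_archetype:
                kind = "archetype"
            elif u < config.p_archetype + config.p_constitutive:
                kind = "constitutive"
            else:
                kind = "background"
        if kind == "archetype":
            a = int(rng.integers(1, len(ARCHETYPES) + 1))
            archetype[r.element_id] = a
            profile = ARCHETYPES[a]
            states = ["active" if x >= 0.5 else "primed" for x in profile]
        elif kind == "constitutive":
            archetype[r.element_id] = 0
            states = ["active"] * len(config.cell_types)
        else:
            archetype[r.element_id] = 0
            fixed = rng.choice(background_states, size=len(config.cell_types), p=background_p)
            states = list(fixed)
        for ct, s in zip(config.cell_types, states):
            state_rows.append({"element_id": r.element_id, "cell_type": ct, "state": s})
    return (
        pd.Series(archetype, name="archetype"),
        pd.DataFrame(state_rows),
    )


def _promoter_programs(
    config: SimulationConfig,
    promoters: ElementSet,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Promoter state per cell type: mostly constitutively active, with
    dynamically repressed, poised and neutral minorities."""
    rows = []
    for e in promoters:
        u = rng.random()
        if u < 0.65:
            states = ["active"] * len(config.cell_types)
        elif u < 0.80:  # dynamically repressed: polycomb in a random block
            start = int(rng.integers(0, len(config.cell_types)))
            width = int(rng.integers(1, len(config.cell_types)))
            states = [
                "repressed" if start <= i < start + width else "active"
                for i in range(len(config.cell_types))
            ]
        elif u < 0.90:
            states = ["poised"] * len(config.cell_types)
        elif u < 0.95:
            states = ["mixed"] * len(config.cell_types)
        else:
            states = ["neutral"] * len(config.cell_types)
        for ct, s in zip(config.cell_types, states):
            rows.append({"element_id": e.element_id, "cell_type": ct, "state": s})
    return pd.DataFrame(rows)


def _noisy_copy(
    peaks: list[NarrowPeak], config: SimulationConfig, rng: np.random.Generator
) -> list[NarrowPeak]:
    out = []
    for p in peaks:
        if rng.random() < config.peak_drop_rate:
            continue
        shift_a = int(rng.normal(0, config.peak_shift_sd))
        shift_b = int(rng.normal(0, config.peak_shift_sd))
        start = max(0, p.start + shift_a)
        end = max(start + 50, p.end + shift_b)
        out.append(p.moved_to(GenomicInterval(p.chrom, start, end)))
    return out


def _emit_peak_sets(
    config: SimulationConfig,
    enhancers: ElementSet,
    promoters: ElementSet,
    enh_states: pd.DataFrame,
    prom_states: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[
    dict[tuple[str, str], ReplicatedPeakCalls],
    dict[tuple[str, str], list[NarrowPeak]],
    dict[str, list[NarrowPeak]],
]:
    """Planted peaks for every mark x cell type, with replicate noise.

    The noise-free planted peaks stand in for the reproducible set; the
    five-way ReplicatedPeakCalls carry drop/jitter noise in the replicate
    and pseudoreplicate channels.
    """
    enh_by_id = enhancers.by_id()
    prom_by_id = promoters.by_id()
    histone_marks = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")

    enh_wide = enh_states.pivot(index="element_id", columns="cell_type", values="state")
    prom_wide = prom_states.pivot(index="element_id", columns="cell_type", values="state")

    reproducible: dict[tuple[str, str], list[NarrowPeak]] = {}
    atac: dict[str, list[NarrowPeak]] = {}
    for ct in config.cell_types:
        planted: dict[str, list[NarrowPeak]] = {m: [] for m in histone_marks}
        atac_ct: list[NarrowPeak] = []
        for eid in enh_wide.index:
            e = enh_by_id[eid]
            s, w = e.summit, 300
            iv = GenomicInterval(e.interval.chrom, s - w, s + w)
            q = float(5 + 95 * rng.random())
            atac_ct.append(
                NarrowPeak(iv, name=f"atac_{ct}_{eid}", q_score=q, p_score=q + 1,
                           summit_offset=w)
            )
            for m in ENHANCER_STATE_FLAGS[enh_wide.loc[eid, ct]]:
                qm = float(4 + 60 * rng.random())
                planted[m].append(
                    NarrowPeak(e.interval, name=f"{m}_{ct}_{eid}", q_score=qm,
                               p_score=qm + 1, summit_offset=len(e.interval) // 2)
                )
        for pid in prom_wide.index:
            e = prom_by_id[pid]
            for m in PROMOTER_STATE_FLAGS[prom_wide.loc[pid, ct]]:
                qm = float(4 + 60 * rng.random())
                planted[m].append(
                    NarrowPeak(e.interval, name=f"{m}_{ct}_{pid}", q_score=qm,
                               p_score=qm + 1, summit_offset=len(e.interval) // 2)
                )
        atac[ct] = atac_ct
        reproducible[("ATAC", ct)] = atac_ct
        for m in histone_marks:
            reproducible[(m, ct)] = planted[m]

    peak_calls: dict[tuple[str, str], ReplicatedPeakCalls] = {}
    for (mark, ct), pooled in reproducible.items():
        assay = "ATAC" if mark == "ATAC" else "histone"
        peak_calls[(mark, ct)] = ReplicatedPeakCalls(
            pooled=list(pooled),
            rep1=_noisy_copy(pooled, config, rng),
            rep2=_noisy_copy(pooled, config, rng),
            pseudo1=_noisy_copy(pooled, config, rng),
            pseudo2=_noisy_copy(pooled, config, rng),
            assay=assay,
        )
    return peak_calls, reproducible, atac


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws; dispersion -> 0 degenerates to Poisson-free rounding."""
    mean = np.asarray(mean, float)
    if dispersion <= 0:
        return np.rint(mean).astype(int)
    size = 1.0 / dispersion
    p = size / (size + np.maximum(mean, 1e-9))
    return rng.negative_binomial(size, p)


def _sample_meta(
    config: SimulationConfig, mark: str, rng: np.random.Generator
) -> tuple[list[SampleMeta], np.ndarray]:
    depth_factors = rng.uniform(0.8, 1.25, size=len(config.cell_types) * config.replicates)
    samples = []
    k = 0
    for ct in config.cell_types:
        for rep in range(1, config.replicates + 1):
            samples.append(
                SampleMeta(
                    sample_id=f"{mark}_{ct}_r{rep}",
                    cell_type=ct,
                    replicate=rep,
                    mark=mark,
                    library_depth=float(depth_factors[k] * 1e7),
                )
            )
            k += 1
    return samples, depth_factors


def simulate_study(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate the complete in-silico study from one seeded config."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    annotation = simulate_annotation(config, rng)
    promoters = build_promoter_set(annotation)
    enhancers, slots = _place_enhancers(config, annotation, rng)
    tf_targets = _pick_targets(config, slots, config.n_genes)
    archetype, enh_states = _assign_programs(config, slots, tf_targets, rng)
    prom_states = _promoter_programs(config, promoters, rng)
    peak_calls, reproducible, atac = _emit_peak_sets(
        config, enhancers, promoters, enh_states, prom_states, rng
    )

    # ---- latent H3K27ac activity per enhancer x cell type -----------------
    cts = list(config.cell_types)
    enh_wide = enh_states.pivot(index="element_id", columns="cell_type", values="state")
    enh_wide = enh_wide.loc[[e.element_id for e in enhancers], cts]
    mean_ac = config.mean_by_state["H3K27ac"]
    base = enh_wide.apply(lambda c: c.map(mean_ac)).astype(float).to_numpy()
    for i, eid in enumerate(enh_wide.index):
        a = archetype.get(eid, 0)
        if a:
            prof = ARCHETYPES[a]
            act = enh_wide.iloc[i].to_numpy() == "active"
            base[i, act] = mean_ac["active"] * (0.5 + prof[act])
    jitter = np.exp(rng.normal(0.0, config.activity_jitter, size=base.shape))
    latent = base * jitter
    latent_df = pd.DataFrame(latent, index=enh_wide.index, columns=cts)

    # ---- H3K27ac counts at enhancers --------------------------------------
    ac_samples, ac_depth = _sample_meta(config, "H3K27ac", rng)
    mean_mat = np.repeat(latent, config.replicates, axis=1) * ac_depth[None, :]
    ac_counts = _nb(rng, mean_mat, config.nb_dispersion)
    enhancer_counts = {
        "H3K27ac": CountMatrix(
            counts=pd.DataFrame(
                ac_counts, index=enh_wide.index, columns=[s.sample_id for s in ac_samples]
            ),
            samples=ac_samples,
            regions={e.element_id: e.interval for e in enhancers},
        )
    }

    # ---- H3K27me3 counts at promoters -------------------------------------
    prom_wide = prom_states.pivot(index="element_id", columns="cell_type", values="state")
    prom_wide = prom_wide.loc[[e.element_id for e in promoters], cts]
    mean_me3 = config.mean_by_state["H3K27me3"]
    base_me3 = prom_wide.apply(lambda c: c.map(mean_me3)).astype(float).to_numpy()
    jit_me3 = np.exp(rng.normal(0.0, config.activity_jitter, size=base_me3.shape))
    me3_samples, me3_depth = _sample_meta(config, "H3K27me3", rng)
    me3_counts = _nb(
        rng,
        np.repeat(base_me3 * jit_me3, config.replicates, axis=1) * me3_depth[None, :],
        config.nb_dispersion,
    )
    promoter_counts = {
        "H3K27me3": CountMatrix(
            counts=pd.DataFrame(
                me3_counts, index=prom_wide.index,
                columns=[s.sample_id for s in me3_samples],
            ),
            samples=me3_samples,
            regions={e.element_id: e.interval for e in promoters},
        )
    }

    # ---- planted links and expression -------------------------------------
    target_genes = set(tf_targets["gene_id"])
    slot0 = slots[slots["slot"] == 0].set_index("gene_id")["element_id"]
    eligible = [
        g for g, eid in slot0.items()
        if archetype.get(eid, 0) > 0 and g not in target_genes
    ]
    n_links = int(round(config.link_fraction * len(eligible)))
    linked_genes = sorted(rng.choice(eligible, size=n_links, replace=False))
    links = pd.DataFrame(
        {"enhancer_id": [slot0[g] for g in linked_genes], "gene_id": linked_genes}
    )

    rna_samples, rna_depth = _sample_meta(config, "RNA", rng)
    gene_ids = list(annotation["gene_id"])
    expr_mean = np.full(
        (len(gene_ids), len(cts)), config.unlinked_expression_mean
    )
    gi = {g: i for i, g in enumerate(gene_ids)}
    for g, eid in zip(links["gene_id"], links["enhancer_id"]):
        expr_mean[gi[g]] = (
            config.expression_base
            + config.link_strength * latent_df.loc[eid].to_numpy()
        )
    expr_counts = _nb(
        rng,
        np.repeat(expr_mean, config.replicates, axis=1) * rna_depth[None, :],
        config.nb_dispersion,
    )
    expression = pd.DataFrame(
        expr_counts, index=gene_ids, columns=[s.sample_id for s in rna_samples]
    )

    # ---- TF experiment -----------------------------------------------------
    tf_peaks, ko_tables = _simulate_tf_experiment(
        config, annotation, slots, tf_targets, rng
    )

    truth = GroundTruth(
        enhancer_states=enh_states,
        promoter_states=prom_states,
        links=links,
        archetype=archetype,
        tf_targets=tf_targets,
    )
    return SimulatedStudy(
        config=config,
        annotation=annotation,
        enhancers=enhancers,
        promoters=promoters,
        truth=truth,
        peak_calls=peak_calls,
        reproducible_peaks=reproducible,
        atac_by_celltype=atac,
        enhancer_counts=enhancer_counts,
        promoter_counts=promoter_counts,
        expression=expression,
        rna_samples=rna_samples,
        tf_peaks=tf_peaks,
        ko_tables=ko_tables,
        enhancer_latent=latent_df,
    )


def _simulate_tf_experiment(
    config: SimulationConfig,
    annotation: pd.DataFrame,
    slots: pd.DataFrame,
    tf_targets: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, list[NarrowPeak]], dict[str, pd.DataFrame]]:
    """TF ChIP peaks per factor plus knockout differential tables.

    Up-target class peaks sit on the gene's slot-0 enhancer (which the
    program assignment forces to be hPGCLC-active); down-target class
    peaks sit 13.5-14.5 kb from the TSS where no element lives; class
    background peaks go to the gene-free tail of chromosome 1.
    """
    ann = annotation.set_index("gene_id")
    slot0 = slots[slots["slot"] == 0].set_index("gene_id")
    tf_peaks: dict[str, list[NarrowPeak]] = {tf: [] for tf in config.tf_names}
    counter = 0

    def add_peak(tf: str, chrom: str, centre: int, half: int) -> None:
        nonlocal counter
        counter += 1
        tf_peaks[tf].append(
            NarrowPeak(
                GenomicInterval(chrom, centre - half, centre + half),
                name=f"{tf}_pk{counter:05d}",
                q_score=float(10 + 90 * rng.random()),
                p_score=100.0,
                summit_offset=half,
            )
        )

    for _, t in tf_targets.iterrows():
        tfs = t["class"].split("+")
        gene = ann.loc[t["gene_id"]]
        if t["direction"] == "up":
            centre = int(slot0.loc[t["gene_id"], "summit"])
            half = 300
        else:
            side = 1 if int(t["gene_id"][1:]) % 2 == 0 else -1
            centre = int(gene["tss"]) + side * int(13_500 + rng.integers(0, 1000))
            half = 200
        for tf in tfs:
            add_peak(tf, str(gene["chrom"]), centre, half)

    # background peaks in the gene-free tail of chr1
    last_tss = int(annotation.loc[annotation["chrom"] == "chr1", "tss"].max())
    cursor = last_tss + 150_000
    names = config.tf_names
    for mask in range(1, 2 ** len(names)):
        members = [n for i, n in enumerate(names) if mask >> i & 1]
        for _ in range(config.background_peaks_per_class):
            if cursor + 400 > config.chrom_length:
                raise ValueError("chromosome too short for background TF peaks")
            for tf in members:
                add_peak(tf, "chr1", cursor + 200, 200)
            cursor += 1200

    # knockout differential tables
    by_dir: dict[str, dict[str, str]] = {"up": {}, "down": {}}
    for _, t in tf_targets.iterrows():
        by_dir[t["direction"]][t["gene_id"]] = t["class"]
    ko_tables = {}
    for tf in config.tf_names:
        lfc = rng.normal(0.0, 0.2, size=len(annotation))
        adj = rng.uniform(0.2, 1.0, size=len(annotation))
        tab = pd.DataFrame(
            {"gene_id": annotation["gene_id"].to_numpy(), "log2_fc": lfc, "adj_p": adj}
        )
        tab = tab.set_index("gene_id")
        for direction, sign in (("up", -1.0), ("down", 1.0)):
            for g, label in by_dir[direction].items():
                if tf in label.split("+"):
                    eff = config.ko_effect + abs(rng.normal(0, config.ko_effect_sd))
                    tab.loc[g, "log2_fc"] = sign * eff
                    tab.loc[g, "adj_p"] = float(rng.uniform(1e-8, 1e-4))
        ko_tables[tf] = tab.reset_index()
    return tf_peaks, ko_tables


def simulate_null_counts(
    n_regions: int,
    samples_per_group: int = 2,
    mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
    group_names: tuple[str, str] = ("A", "B"),
) -> CountMatrix:
    """NB counts with no group difference — the differential test's null."""
    rng = np.random.default_rng(seed)
    depth = rng.uniform(0.8, 1.25, size=2 * samples_per_group)
    counts = _nb(
        rng,
        np.full((n_regions, 2 * samples_per_group), mean) * depth[None, :],
        dispersion,
    )
    samples = []
    for gi, g in enumerate(group_names):
        for rep in range(1, samples_per_group + 1):
            j = gi * samples_per_group + rep - 1
            samples.append(
                SampleMeta(
                    sample_id=f"{g}_r{rep}", cell_type=g, replicate=rep,
                    mark="H3K27ac", library_depth=float(depth[j] * 1e7),
                )
            )
    return CountMatrix(
        counts=pd.DataFrame(
            counts,
            index=[f"r{i:05d}" for i in range(n_regions)],
            columns=[s.sample_id for s in samples],
        ),
        samples=samples,
    )


def emit_fragments(
    study: SimulatedStudy,
    mark: str = "H3K27ac",
    fragment_length: int = 200,
    seed: int | None = None,
) -> dict[str, list[GenomicInterval]]:
    """Fragment intervals consistent with the count matrix.

    For every element x sample, emits exactly ``count`` fragments fully
    inside the element, so re-counting them at the (disjoint) elements
    reproduces the matrix.
    """
    cm = (
        study.enhancer_counts.get(mark)
        or study.promoter_counts.get(mark)
    )
    if cm is None or cm.regions is None:
        raise ValueError(f"no count matrix with regions for mark {mark}")
    rng = np.random.default_rng(study.config.seed + 17 if seed is None else seed)
    out: dict[str, list[GenomicInterval]] = {}
    for sid in cm.counts.columns:
        frags = []
        for rid, k in cm.counts[sid].items():
            iv = cm.regions[rid]
            span = max(1, len(iv) - fragment_length)
            for start in rng.integers(iv.start, iv.start + span, size=int(k)):
                frags.append(
                    GenomicInterval(iv.chrom, int(start), int(start) + fragment_length)
                )
        out[sid] = frags
    return out
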