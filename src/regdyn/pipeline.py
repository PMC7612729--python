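"""End-to-end pipeline: simulate -> reproducible peaks -> elements ->
classification -> dynamics -> linking -> TF targets.

Every stage writes plain-text outputs under the run directory and records
a SHA-256 content hash in ``manifest.json``; rerunning with the same
configuration reproduces identical hashes. No stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as rio
from .elements import StateRules, build_enhancer_set, build_promoter_set, classify_elements, state_transitions
from .linking import link_enhancers_to_genes
from .reproducible import filter_by_qscore, retain_reproducible
from .signal import CELL_TYPES, cluster_dynamic, differential_signal, normalize, select_dynamic_elements
from .simulate import SimulatedStudy, SimulationConfig, simulate_study
from .tf import TfPeakCollection, call_direct_targets, intersect_tf_peaks
from .intervals import GenomicInterval, NarrowPeak

logger = logging.getLogger(__name__)

STAGES = ["simulate", "repro", "elements", "classify", "dynamics", "link", "tf"]

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    outdir: str = "regdyn_run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    trajectory: tuple[str, ...] = tuple(CELL_TYPES)
    contrasts: list[tuple[str, str]] | None = None  # default: consecutive pairs
    k_enhancer_clusters: int = 9
    k_promoter_clusters: int = 7
    cluster_seed: int = 0
    min_overlap_frac: float = 0.2
    tau_min: float = 0.3
    p_max: float = 0.05
    max_link_distance: int = 100_000
    state_rules_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        contrasts = raw.pop("contrasts", None)
        if contrasts is not None:
            contrasts = [tuple(c) for c in contrasts]
        return cls(simulation=sim, contrasts=contrasts, **raw)

    def consecutive_contrasts(self) -> list[tuple[str, str]]:
        if self.contrasts is not None:
            return list(self.contrasts)
        return list(zip(self.trajectory[:-1], self.trajectory[1:]))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[Path] = []
        self.warnings = 0
        self.study: SimulatedStudy | None = None
        self.artifacts: dict = {}

    def emit(self, rel: str, writer) -> None:
        path = self.outdir / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        self.files.append(path)

    def need(self, key: str, stage: str) -> object:
        if key not in self.artifacts:
            raise RuntimeError(
                f"stage requires missing artifact {key!r}: run stage {stage!r} first"
            )
        return self.artifacts[key]


def _stage_simulate(run: _Run) -> None:
    study = simulate_study(run.config.simulation)
    run.study = study
    run.artifacts["study"] = study
    run.emit("annotation.tsv", lambda p: rio.write_gene_table(study.annotation, p))
    run.emit(
        "truth/enhancer_states.tsv",
        lambda p: study.truth.enhancer_states.to_csv(p, sep="\t", index=False),
    )
    run.emit(
        "truth/links.tsv", lambda p: study.truth.links.to_csv(p, sep="\t", index=False)
    )
    run.emit(
        "truth/tf_targets.tsv",
        lambda p: study.truth.tf_targets.to_csv(p, sep="\t", index=False),
    )
    for (mark, ct), calls in study.peak_calls.items():
        run.emit(
            f"peaks/{mark}_{ct}_pooled.narrowPeak",
            lambda p, c=calls: rio.write_narrowpeak(c.pooled, p),
        )


def _stage_repro(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    repro: dict[tuple[str, str], list[NarrowPeak]] = {}
    for (mark, ct), calls in study.peak_calls.items():
        kept = retain_reproducible(calls)
        kept = filter_by_qscore(kept, calls.assay)
        repro[(mark, ct)] = kept
        run.emit(
            f"repro/{mark}_{ct}.narrowPeak",
            lambda p, k=kept: rio.write_narrowpeak(k, p),
        )
    run.artifacts["repro"] = repro


def _stage_elements(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    promoters = build_promoter_set(study.annotation)
    # the noise-free ATAC channel defines the open-chromatin universe
    enhancers = build_enhancer_set(
        study.atac_by_celltype, promoters, flank=study.config.enhancer_flank
    )
    run.artifacts["promoters"] = promoters
    run.artifacts["enhancers"] = enhancers
    run.emit(
        "elements/promoters.bed",
        lambda p: rio.write_bed(
            promoters.intervals(), p, names=[e.element_id for e in promoters]
        ),
    )
    run.emit(
        "elements/enhancers.bed",
        lambda p: rio.write_bed(
            enhancers.intervals(), p, names=[e.element_id for e in enhancers]
        ),
    )


def _stage_classify(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    enhancers = run.need("enhancers", "elements")
    promoters = run.need("promoters", "elements")
    rules = (
        StateRules.from_yaml(run.config.state_rules_file)
        if run.config.state_rules_file
        else StateRules.default()
    )
    marks = study.reproducible_peaks
    enh_assign = classify_elements(
        enhancers, marks, cell_types=list(run.config.trajectory),
        min_overlap_frac=run.config.min_overlap_frac, rules=rules,
    )
    prom_assign = classify_elements(
        promoters, marks, cell_types=list(run.config.trajectory),
        min_overlap_frac=run.config.min_overlap_frac, rules=rules,
    )
    run.artifacts["enh_assign"] = enh_assign
    run.artifacts["prom_assign"] = prom_assign
    run.emit(
        "states/enhancer_states.tsv",
        lambda p: enh_assign.to_csv(p, sep="\t", index=False),
    )
    run.emit(
        "states/promoter_states.tsv",
        lambda p: prom_assign.to_csv(p, sep="\t", index=False),
    )
    mats = state_transitions(enh_assign, list(run.config.trajectory))
    for tm in mats:
        run.emit(
            f"states/transitions_{tm.source_cell_type}_{tm.target_cell_type}.tsv",
            lambda p, t=tm: t.counts.to_csv(p, sep="\t"),
        )


def _stage_dynamics(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    enh_assign: pd.DataFrame = run.need("enh_assign", "classify")
    cm = normalize(study.enhancer_counts["H3K27ac"])
    run.artifacts["ac_norm"] = cm
    diffs = {}
    for a, b in run.config.consecutive_contrasts():
        d = differential_signal(cm, (a, b))
        diffs[(a, b)] = d
        run.emit(
            f"dynamics/diff_{a}_{b}.tsv", lambda p, x=d: x.to_csv(p, sep="\t", index=False)
        )
    dynamic = select_dynamic_elements(enh_assign, diffs, state_predicate=("active",))
    run.artifacts["dynamic"] = dynamic
    sub = cm.normalized.loc[sorted(dynamic)]
    labels, profiles = cluster_dynamic(
        sub, k=run.config.k_enhancer_clusters, seed=run.config.cluster_seed
    )
    run.artifacts["clusters"] = labels
    run.emit("dynamics/dynamic_enhancers.txt",
             lambda p: p.write_text("".join(f"{e}\n" for e in sorted(dynamic))))
    run.emit("dynamics/clusters.tsv", lambda p: labels.to_csv(p, sep="\t"))
    run.emit("dynamics/cluster_profiles.tsv", lambda p: profiles.to_csv(p, sep="\t"))


def _stage_link(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    enhancers = run.need("enhancers", "elements")
    cm = run.artifacts.get("ac_norm") or normalize(study.enhancer_counts["H3K27ac"])
    expr = normalize_expression(study)
    links = link_enhancers_to_genes(
        enhancers,
        cm.normalized,
        expr,
        study.annotation,
        max_distance=run.config.max_link_distance,
        tau_min=run.config.tau_min,
        p_max=run.config.p_max,
    )
    run.artifacts["links"] = links
    run.emit("links/links.tsv", lambda p: links.to_csv(p, sep="\t", index=False))


def normalize_expression(study: SimulatedStudy) -> pd.DataFrame:
    """log2(depth-normalized expression + 1), columns renamed to match the
    H3K27ac sample order (cell type x replicate)."""
    from .signal import CountMatrix, normalize as _norm

    cm = CountMatrix(counts=study.expression, samples=study.rna_samples)
    normed = _norm(cm).normalized
    ac_cols = study.enhancer_counts["H3K27ac"].counts.columns
    mapping = dict(zip(sorted(normed.columns), sorted(ac_cols)))
    # both follow <mark>_<celltype>_r<rep>; align by (cell type, replicate)
    key = {s.sample_id: (s.cell_type, s.replicate) for s in study.rna_samples}
    ac_key = {
        s.sample_id: (s.cell_type, s.replicate)
        for s in study.enhancer_counts["H3K27ac"].samples
    }
    inv = {v: k for k, v in ac_key.items()}
    normed = normed.rename(columns={c: inv[key[c]] for c in normed.columns})
    return normed[list(ac_cols)]


def _stage_tf(run: _Run) -> None:
    study: SimulatedStudy = run.need("study", "simulate")
    enh_assign: pd.DataFrame = run.need("enh_assign", "classify")
    prom_assign: pd.DataFrame = run.need("prom_assign", "classify")
    enhancers = run.need("enhancers", "elements")
    promoters = run.need("promoters", "elements")

    collections = [
        TfPeakCollection(tf, peaks) for tf, peaks in study.tf_peaks.items()
    ]
    classes, pairwise = intersect_tf_peaks(collections)
    run.emit(
        "tf/classes.tsv",
        lambda p: classes[["label", "count"]].to_csv(p, sep="\t", index=False),
    )
    run.emit("tf/pairwise.tsv", lambda p: pairwise.to_csv(p, sep="\t", index=False))

    context = "hPGCLC"
    by_id = {**enhancers.by_id(), **promoters.by_id()}
    def _ivs(assign: pd.DataFrame, states: set[str]) -> list[GenomicInterval]:
        sel = assign[(assign["cell_type"] == context) & assign["state"].isin(states)]
        return [by_id[e].interval for e in sel["element_id"]]

    active = _ivs(enh_assign, {"active"}) + _ivs(prom_assign, {"active"})
    actmix = _ivs(enh_assign, {"active", "mixed"}) + _ivs(prom_assign, {"active", "mixed"})

    class_peaks = {
        row["label"]: [
            NarrowPeak(iv, name=f"{row['label']}_{i}", summit_offset=len(iv) // 2)
            for i, iv in enumerate(row["regions"])
        ]
        for _, row in classes.iterrows()
    }
    targets = call_direct_targets(
        class_peaks, study.ko_tables, active, actmix, study.annotation
    )
    run.artifacts["direct_targets"] = targets
    run.emit("tf/direct_targets.tsv", lambda p: targets.to_csv(p, sep="\t", index=False))


_STAGE_FN = {
    "simulate": _stage_simulate,
    "repro": _stage_repro,
    "elements": _stage_elements,
    "classify": _stage_classify,
    "dynamics": _stage_dynamics,
    "link": _stage_link,
    "tf": _stage_tf,
}


def run_pipeline(config: RunConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the selected stages in dependency order and write a manifest.

    Returns the manifest: config echo, per-output SHA-256 hashes and a
    warning count. Missing upstream artifacts raise an error naming the
    stage to run first.
    """
    chosen = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    unknown = set(stages or []) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    run = _Run(config)
    counter = _WarningCounter()
    logging.getLogger("regdyn").addHandler(counter)
    try:
        for s in chosen:
            logger.info("stage %s", s)
            _STAGE_FN[s](run)
    finally:
        logging.getLogger("regdyn").removeHandler(counter)

    manifest = {
        "stages": chosen,
        "config": _config_dict(config),
        "warnings": counter.count,
        "outputs": {
            str(p.relative_to(run.outdir)): _sha256(p) for p in sorted(run.files)
        },
    }
    (run.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["simulation"]["mean_by_state"] = {
        k: dict(v) for k, v in d["simulation"]["mean_by_state"].items()
    }
    return d
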