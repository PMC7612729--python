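"""Enhancer-to-gene linking with the empirical same-chromosome null.

Each enhancer is assigned to its nearest gene (< 100 kb summit-to-TSS),
scored by Kendall's tau-b between its H3K27ac signal and the gene's
expression across the 12 samples, and tested against the taus of all
other genes on the chromosome. High confidence = tau >= 0.3 and
empirical p <= 0.05. Recovery is then measured against the planted links.
"""

from regdyn import SimulationConfig, link_enhancers_to_genes, normalize, simulate_study
from regdyn.pipeline import normalize_expression

study = simulate_study(SimulationConfig(seed=0, n_genes=100, n_enhancers=600,
                                        targets_per_class=1))
cm = normalize(study.enhancer_counts["H3K27ac"])
links = link_enhancers_to_genes(
    study.enhancers, cm.normalized, normalize_expression(study), study.annotation
)

hc = links[links.high_confidence]
print(f"candidate pairs: {len(links)}; high-confidence: {len(hc)}")
print(hc.head().round(3).to_string(index=False))

truth = set(map(tuple, study.truth.links.values))
called = set(map(tuple, hc[["enhancer_id", "gene_id"]].values))
evaluated = set(map(tuple, links[["enhancer_id", "gene_id"]].values))
print(f"\nplanted links: {len(truth)}")
print(f"sensitivity:   {len(truth & called) / len(truth):.2f}")
print(f"false-link rate among non-planted pairs: "
      f"{len(called - truth) / len(evaluated - truth):.3f}")
print("\nA planted link shares a latent activity between the enhancer's")
print("H3K27ac and the gene's expression, so its tau stands above the")
print("chromosome-wide null; unlinked pairs pass the gate only rarely.")
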