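# Methods

This note documents the models, rules and numerical choices behind each
stage of `regdyn`, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and formats

All intervals are 0-based half-open (`[start, end)`), the BED/narrowPeak
dialect. Peak summits are stored as offsets from the interval start
(narrowPeak column 10); `-1` means no summit, and consumers fall back to
the interval centre. Abutting intervals (`a.end == b.start`) merge, the
bedtools default. p/q significance travels as −log10 values, so larger
is more significant.

## Reproducible peak retention

Input is the five-way peak calling per mark and cell type: two
biological replicates, the pooled replicates, and two pooled
pseudoreplicates (each built upstream from a random half of all reads).
A pooled peak is retained iff

    (cov(P, rep1) ≥ f AND cov(P, rep2) ≥ f)
    OR (cov(P, pseudo1) ≥ f AND cov(P, pseudo2) ≥ f)

where `cov(P, S)` is the fraction of P's own length covered by the
*union* of set S (multiple supporting peaks never double-count), and
f = 0.20 for ATAC, 0.30 for histone marks. The test is anchored on the
pooled peak; a `reciprocal` option additionally requires some supporting
peak to be covered ≥ f by P. The subsequent confidence filter keeps
q_score strictly above 4.0 (ATAC; FDR < 1e-4) or 3.0 (histone;
FDR < 1e-3) — the boundary is excluded because the FDR bound is a strict
inequality. Pseudoreplicate *generation* is read-level processing and is
out of scope; the generator fabricates concordant/discordant sets
instead.

## Element construction

Promoters: TSS ± 1 kb for protein-coding and lincRNA transcripts, with
identical windows collapsed to one element that remembers all its
transcripts; windows are clipped at position 0 with a counted warning.

Enhancers: per-cell-type ATAC peaks with q_score > 4 are merged across
cell types into combined open regions; each region's representative
summit is the constituent summit with the highest q (ties to the
leftmost coordinate); regions overlapping any promoter window by ≥ 1 bp
are removed (the removal is unconditional, not the 20% rule — distal
means outside TSS ± 1 kb); surviving summits are extended ± 500 bp;
overlapping windows merge, and the merged element keeps its best
constituent summit. Element ids are assigned in (chrom, start) order.

## State classification

A mark is *present* at an element in a cell type when its peak set
covers ≥ 20% of the element length. The mark-combination → state map is
a config file (`src/regdyn/data/state_rules.yaml`), not code: the
mapping for two combinations (H3K27ac alone, and all three marks) is a
judgement call, so it is shipped versioned and overridable. The
defaults: acetylation without H3K27me3 is `active` (with or without
H3K4me1/3); acetylation with H3K27me3 is `mixed`; H3K4me1 alone is
`primed` (enhancers; for promoters H3K4me3 alone is `active` — there is
no primed promoter state); H3K4me1/3 plus H3K27me3 without acetylation
is `poised`; H3K27me3 alone is `repressed`; no mark is `neutral`.
Classification is a pure function of the presence flags, so permuting
elements never changes a state. Transition matrices between consecutive
cell types are plain cross-tabulations whose marginals equal the
per-cell-type state tallies by construction.

## Counts, normalization and differential signal

Counting follows featureCounts `-f -p -O` semantics: a fragment
increments *every* region it overlaps by ≥ 1 bp. Analysis bins are 1-kb
genome tiles kept when they touch a combined peak. The default size
factor is relative library depth, s_j = depth_j / geomean(depths), with
median-of-ratios selectable; normalized values are log2(count/s_j + 1),
which preserves within-sample rank order.

Differential signal between two cell types (2 replicates each) uses a
negative-binomial Wald test authored here (deliberately not a wrapper
around an external DE package, and not equivalent to one — no fold-change
shrinkage):

1. counts are scaled to a common baseline, q_ij = K_ij / s_j;
2. per-region dispersion by method of moments from the within-group
   residual variance pooled across the contrast:
   α̂ = max(0, (v − m̄·avg(1/s_j)) / m̄²), v the pooled residual variance
   (n − 2 df), m̄ the overall scaled mean;
3. α̂ is moderated toward the median dispersion across regions with
   prior_df = 10: α = (2·α̂ + 10·α_central)/12. With two replicates per
   group the raw estimate has only 2 df; sharing information across
   regions is what makes the test usable. An unmoderated normal Wald
   test was measurably anticonservative under the simulated null
   (type-I ≈ 0.068 at nominal 0.05) and an unmoderated t(2) reference
   both over-conservative (≈ 0.017) and essentially powerless for
   isolated effects after BH correction; the moderated t gives type-I
   ≈ 0.045 across seeds with full power on planted 8-fold changes;
4. Wald statistic for log2(m_B + ½) − log2(m_A + ½) with a delta-method
   standard error, referred to t(n − 2 + prior_df); BH adjustment across
   regions. The pseudocount ½ only matters for near-zero means.

A region is *dynamic* when |log2FC| > 1 and adjusted p < 0.05. The
contrasts used to define "dynamic somewhere" default to consecutive
trajectory pairs and are a config input. Dynamically active enhancers
are those active in ≥ 1 cell type and dynamic in ≥ 1 contrast, minus
those active in all six (constitutive). k-means runs on per-element
z-scores across all 12 samples (constant rows become zeros), k-means++
with 25 restarts and a recorded seed; k defaults to 9 for enhancer
H3K27ac and 7 for the promoter H3K27me3 variant. The promoter-mark AUC
is Mann–Whitney U scaled to [0, 1] (midranks on ties), positives being
the promoters of the top- or bottom-1000 expressed genes among
non-neutral promoters.

## Enhancer–gene linking

Candidate pairs are nearest-gene assignments with summit→TSS distance
strictly below 100 kb (ties: smaller distance, then lexicographic gene
id). The score is Kendall's τ-b — computed here by direct all-pairs
concordance counting with tie correction, exact for n = 12 and verified
against an independent implementation — between the enhancer's
log-normalized H3K27ac and the gene's log-normalized expression. The
null for each enhancer is its τ against every other gene on the same
chromosome; the focal gene is excluded by default so the observed value
cannot support itself, and the empirical p is the literal count/N (a
`(k+1)/(N+1)` option exists). Genes below a configurable mean-expression
floor can be dropped from both the candidates and the null (default: no
floor; the simulated genes are all expressed). Pairs with undefined τ
(constant vectors) are dropped with a warning. High confidence is
τ ≥ 0.3 AND p ≤ 0.05, both boundaries inclusive as printed.

Because all enhancers on a chromosome are tested against the same gene
panel, empirical p-values of different pairs are not independent; a
uniformity test over pairs treats them as if they were, so occasional
small KS p-values at some simulation seeds are expected even under a
perfect null. The per-pair p-values themselves are calibrated.

## TF cooperativity and direct targets

The merged universe of the three TF peak sets is partitioned into the 7
non-empty classes by ≥ 1 bp overlap with each TF's peaks; counts sum to
the universe size by construction. Pairwise overlap significance is the
upper-tail hypergeometric P[X ≥ k] (the `phyper(k−1, lower.tail=FALSE)`
convention), with the universe supplied explicitly — the same statistic
serves generic region-set enrichment, where the reported fraction is the
share of query regions touching the reference.

Regulatory potential of gene g for a TF: Σ over the TF's peak summits
within 100 kb of g's TSS of w(Δ) = exp(−(0.5 + 4Δ)), Δ = |distance|/100
kb. The decay is a config entry with this default; its absolute scale is
arbitrary (only ranks enter the KS comparison) and the tests therefore
assert the configured form's own closed-form values, additivity and
monotonicity rather than any external constant. Activator/repressor
character: one-tailed two-sample KS of each response group's potentials
against the unchanged group, testing the group stochastically larger;
groups under 5 genes are flagged unreliable.

Direct targets are called per cooperativity class: *up* requires KO
down-regulation (log2FC < −1, adj p < 0.05) in **every** member TF of
the class, a class peak summit within 100 kb of the TSS, and at least
one such peak on an active-or-mixed element in the context cell type;
*down* mirrors with KO up-regulation and **no** nearby class peak on an
active element. Requiring every member TF's KO is the conservative
reading of class-resolved ("alone or cooperatively") evidence. KO tables
are opaque inputs with their own provenance; timepoint differences
between knockouts are not modelled.

## The synthetic study

The generator emulates the statistical structure of the profiled
trajectory, not sequencing: 6 cell types × 2 replicates; genes placed
with ≥ 30 kb TSS spacing; up to 8 enhancer slots per gene at 2.5–11 kb
from the TSS (always distal, always nearest to their anchor gene; the
windows never overlap each other, so planted elements survive
construction unchanged). Enhancer state programs mix 9 activity
archetypes (six cell-type-specific, two ramps, one germline; ~50%),
constitutively active (~10%) and static background states. Mark peaks
are emitted from the planted state through the same canonical
combinations the truth table maps back, making the noise-free channel
exactly invertible; replicate and pseudoreplicate channels drop peaks at
5% and jitter boundaries by N(0, 30 bp).

Counts are negative binomial (dispersion 0.05) around a latent activity
= state mean × archetype activity × exp(N(0, 0.6)) shared per
(element, cell type); the log-normal jitter is the biological variation
that replicates share. A planted link wires a gene's expression mean to
its enhancer's latent activity (expression = 20 + latent), so the link
is discoverable by rank correlation exactly to the extent the shared
latent survives both NB noises; unlinked genes have flat mean 100. The
jitter sd was calibrated once against the linking stage (0.4 left
planted-link sensitivity straddling 0.8 because same-archetype genes
populate the empirical null; 0.6 yields 0.88–0.95 across seeds) and
frozen. TF up-targets get class peaks on their gene's slot-0 enhancer,
which the program assignment forces to be hPGCLC-active; down-target
peaks sit 13.5–14.5 kb from the TSS where no element lives; background
class peaks fill the gene-free chromosome tail; targets are spaced ≥ 4
genes apart so no class peak falls within 100 kb of another target.
KO tables carry planted |log2FC| ≈ 1.8–2.7 at adj p ≤ 1e-4 on target
genes and N(0, 0.2) noise elsewhere.

What it does **not** emulate — and what passing tests therefore do not
show about real data: mappability and GC structure, peak-width and
signal-to-noise heterogeneity, copy-number effects, distance-dependent
enhancer–promoter contact frequencies, shared confounding between
chromatin and expression (batch), three-dimensional skipping of the
nearest gene, or pseudoreplicate construction from reads. Recovery rates
on the simulation are upper bounds tied to its planted effect sizes.

Default scale: 2 chromosomes × 10 Mb, 300 genes, 2,000 enhancers — the
full pipeline, including the replicate-retention pass over every
mark × cell type, runs in ~2 minutes on one CPU; the test suite scales
some fixtures down (60–125 genes) for speed. Identical config and seed
reproduce byte-identical outputs; the pipeline manifest records SHA-256
hashes of every file to make this checkable.

## Degenerate inputs and tie-breaks

Malformed intervals (start ≥ end) are rejected naming the record; empty
pooled peak sets return empty with a counted warning; zero-depth samples
and empty null gene sets are hard errors; missing mark×cell-type peak
sets fail classification loudly rather than defaulting to neutral;
constant vectors give τ = NaN and drop the pair with a warning; summit
ties resolve to the leftmost coordinate; nearest-gene ties to the
smaller distance then lexicographic id; k-means with k larger than the
element count is an error.

## Known limitations

The differential test is a moderated Wald approximation, adequate for
the |log2FC| > 1 gate it feeds but not a substitute for a full GLM at
larger designs; the empirical link p has resolution 1/N_null and is
reported unsmoothed by default; the KS uniformity diagnostic over pairs
ignores their dependence (see above); and the truth-table classifier is
deliberately rule-based — borderline mark coverage flips states at the
20% threshold with no notion of uncertainty.
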