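# Methods

This note documents the models and procedures implemented in `scgpcr`, the
choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Detection and the LoD expression scale

A qPCR entry is *detected* when its Ct is finite and strictly below the
limit of detection (`lod_ct`, default 24 cycles). Detected entries map to
`2**(lod_ct - ct)`; no-amplification entries and entries at or beyond the
limit map to exactly 0. Ct = 24 would give 2^0 = 1 under the formula, but
the limit is by definition where detection ends, so such entries are
censored to 0; stored values therefore are either 0 or ≥ the smallest
detected value, and the transform is exactly invertible on detected
entries (Ct = lod_ct − log2(value)). Jitter of undetected values "around
zero" is a plotting device only and never enters stored data.

## Identity gating

Rules are applied in a fixed order per cell: (1) *QC failure* if a
reference gene does not amplify — both *Gapdh* and *Hprt* are required by
default (the stricter reading; `qc_require_all=False` relaxes to
any-of); (2) *other_markers* if any lineage-exclusion marker amplifies;
(3) identity by target markers. Exactly one detected target marker gives
`cdh5_only` / `myh11_only`. Double target-positives are excluded and
counted under `other_markers` with a separate diagnostic sub-count: the
exclusive "only" identity categories admit a single marker, and exclusion
is the conservative choice for cells of ambiguous identity.

Aortic endothelium poses a special case: all *Cdh5*-positive aortic cells
co-amplify trace *Myh11*. The `allow_low_cross_marker` exception retains a
cell whose wrong-lineage marker is detected but weak, defined as
LoD-scale expression ≤ a configurable absolute threshold. The default,
16 (= 2^4, within four cycles of the limit), is a package choice — no
published numeric cutoff exists for "low" — and is surfaced in the config
and in reports.

The contamination table reports label percentages per sample group over
cells passing QC (failed cDNAs say nothing about sorting purity), so rows
sum to 100.

## Heterogeneity statistics

Frequencies are detected fractions per gene. Receptors-per-cell counts
detected GPCRs restricted to intron-spanning primer designs: single-exon
assays amplify residual genomic DNA and are excluded from the analyzable
set (in the default synthetic panel, 132 of 154). Summaries are
mean ± s.e.m. with s.e.m. = s.d./√n (sample s.d., no finite-population
correction). Group comparisons default to the classic equal-variance
two-sample t-test (Welch via flag); data normalized to a control group are
tested against 1 by a one-sample t-test; two samples with zero variance
and equal means return p = 1 by convention.

## Clustering and cluster-specific genes

Cells are optionally rescaled to the median per-cell total (zeros
preserved; all-zero cells dropped with a warning). The feature space is
the cell × cell Pearson correlation matrix of log2(x+1) profiles — the
log stabilizes the 2^0..2^14 dynamic range (raw-scale and Spearman
variants via flags) — so k-means operates on Euclidean distances between
correlation-matrix rows. Constant-profile cells get correlation 0 against
all others, and a feature matrix whose off-diagonal is constant (all cells
mutually indistinguishable) short-circuits to a single degenerate cluster
with a warning. The best of `n_restarts` (default 50) k-means runs by
within-cluster sum of squares is kept; results are deterministic given the
seed, and labels are renumbered by first appearance. With `k='auto'` the
cluster count maximizes the Calinski–Harabasz score over 2..k_max; the
criterion is pluggable, and planned contrasts should pass an explicit k.

Cluster-specific genes use an exact binomial test on transcript-count
proxies: LoD-scale values are rounded to pseudo-counts; for cluster c and
gene g, the observed count n_gc is referred to Binomial(N_c, π_g) with
N_c the cluster's total count and π_g the gene's global count share, and
the two-sided p is min(1, 2·min(lower tail, upper tail)) — exact, not
normal-approximated, because per-cluster totals can be small. A gene is
*significant* at raw p < α (default 0.05, matching reported raw-P usage;
Benjamini–Hochberg via flag) **and** fold change (cluster mean / all-cells
mean) > 1.5 or < 0.7. Genes undetected globally are excluded. Two caveats
are deliberate and documented rather than hidden:

* the test conditions on π_g estimated from the same data; when a cluster
  holds a large share of all cells this makes the test conservative
  (variance is overstated by roughly 1/(1 − N_c/N));
* the binomial model assumes transcript-level sampling. qPCR-derived
  pseudo-counts arrive in per-cell lumps and are overdispersed relative to
  that model, so on real data raw p-values are anti-conservative and the
  fold-change filter carries much of the control. The calibration tests
  therefore use Poisson-count populations, which satisfy the test's own
  sampling assumptions; they demonstrate correctness of the statistic, not
  calibration on arbitrary data.

t-SNE embeds the same feature rows in 2-D; perplexity defaults to
min(30, (n−1)/3) and runs are deterministic given the embedding seed.

## Co-expression networks

Spearman's rank correlation (Pearson on average ranks; ties receive
average ranks) over retained cells, all gene pairs. Undetected values
enter as zeros — ties the rank transform handles naturally, consistent
with frequency-driven co-expression — with a detected-only mode via flag.
The default edge rule keeps ρ > 0.3 signed, matching the display
convention the threshold comes from; an absolute-value mode exists for
anti-correlation analyses. Edge lists are written sorted by endpoint pair
for deterministic output. Constant genes have undefined ρ and contribute
no edges.

## Promoter TFBS enrichment

Position frequency matrices (JASPAR text, bracketed or plain four-row
dialect, auto-detected) are scored as log2 odds with pseudocount
smoothing against background base frequencies recomputed from the supplied
promoter set (uniform or explicit backgrounds via argument). Each promoter
— by convention 1 kb covering [TSS−950, TSS+50) on the gene's strand — is
scanned on both strands at every offset; the best window score is min–max
normalized by the PWM's attainable range so scores are comparable across
motifs. Windows containing N are skipped; a promoter with no scoreable
window is missing. A gene set is tested against the global promoter set by
z = (x̄_set − x̄_global)/(s_global/√n_set) with a two-sided normal p; for
heat-map export p is transformed to a signed normal quantile
(± Φ⁻¹(1 − p/2), clipped at ±8, sign by direction). The statistic assumes
the set mean is approximately normal (fine for n ≥ ~10 given the
best-hit score distribution) and ignores the without-replacement
correction, which slightly inflates |z| when the set is a large fraction
of the background; a Welch-t alternative can be plugged in. P-values are
raw, matching the P < 0.05 usage upstream.

## NanoString normalization

Fixed order: (1) each lane is scaled by (arithmetic mean over lanes of the
positive-control geometric means) / (its own positive geometric mean) —
the platform's conventional target constant; scale factors are therefore
identifiable only up to that across-lane constant; (2) per lane,
background = mean + 2 s.d. (sample s.d., 8 negative controls required;
configurable leniency) is subtracted, flooring at 0 since counts cannot be
negative; (3) corrected values below 20 are fixed to the constant 20 and
flagged as not expressed (an alternate mode sets them to the lane's
computed background). The <20 rule is applied after background
subtraction, following the stated order of operations. geNorm stability:
V_jk = s.d. over samples of log2(count_j/count_k), M_j = mean of V_jk over
k ≠ j, returned ascending; being ratio-based, M is invariant to per-sample
rescaling. Reference-gene normalization itself is deliberately not
applied — the stability screen is the tool for deciding whether it would
be justified.

## Synthetic data generator

The generator emulates the structure of single-cell qPCR data, not its
full biology. Per (subpopulation, gene), detection is Bernoulli with
probability p_gk; detected Ct values are Normal(μ_gk, σ) truncated to
(0, lod_ct) (σ = 1.5 cycles by default; truncation rather than rejection
keeps generation O(cells × genes) and mirrors the observed 2^0..2^14
expression range). Reference genes amplify in every cell and target
markers in every pure cell near Ct 14. Contaminants are drawn i.i.d. at
the configured rate; they lack the target marker and carry one random
lineage marker (80% of contaminants) or no marker at all (20%) — shaped
like observed contamination tables, where lineage-positive contaminants
dominate. Default detection probabilities follow a zero-inflated Beta
spectrum (≈40% never-detected genes, the rest Beta(0.6, 1.6)), giving few
near-ubiquitous and many rare genes as observed on real panels.

The clustered benchmark plants three subpopulations of 60/57/29 cells
(sizes mirroring a published three-group contrast) with 20 private genes
each detected at 0.8 versus 0.2 elsewhere — a 4-fold separation in mean
expression. Correlated pairs use a Gaussian copula pushed through the
detection/censoring model, so the output Spearman approaches
(6/π)·arcsin(ρ/2). Promoters are i.i.d. background sequence with one
PWM-sampled instance per planted gene at uniform position and strand; the
planted motif uses sharp (low-concentration Dirichlet) columns because
recovery benchmarks presuppose an informative motif — a near-uniform PWM
is unrecoverable by construction. NanoString lanes share one endogenous
profile attenuated per lane, positives on a fixed geometric ladder,
negatives Poisson around the background level; the truth records both the
requested factors and the rescaled (`f · mean(1/f)`) factors that spike
normalization can identify.

Known simplifications: dropout is independent per (cell, gene) and
uncoupled from expression level (no zero-inflation/mean coupling, no
amplification-efficiency variation, no doublets); promoter backgrounds are
i.i.d. (no CpG structure or repeats); NanoString noise is pure Poisson.
Passing benchmarks therefore demonstrates correctness of the statistics
and plumbing under these models, not robustness to every artefact of real
instruments.

## Problem sizes and determinism

The built-in benchmarks run at desk scale — 500 gated cells, 146-cell
clustering, 10,000-test null calibrations, 1,000 background promoters,
three-lane NanoString — sizes at which every planted effect is
comfortably identifiable while the whole suite completes in well under a
minute. Every generator and every stage is bit-reproducible given its
seed; the pipeline manifest records config, input digests and seeds so a
rerun reproduces deterministic stage outputs byte for byte (the manifest
itself carries wall-clock fields and is excluded from byte comparison).
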