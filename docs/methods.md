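# Methods

This note records the models implemented in `spikenet`, the defaults
and why they were chosen, what the synthetic generator does and does
not emulate, and the numerical decisions taken where the design was
genuinely open.

## Data model and TPM

Expression is held as a genes × samples matrix with a sample sheet
(stage, replicate). TPM conversion uses
`TPM_g = 10^6 (c_g/l_g) / Σ_j (c_j/l_j)` per sample. Gene length
defaults to the annotated span `end − start + 1`; an explicit
`length_bp` column takes precedence, because exon-union lengths cannot
be reconstructed from a span alone and callers quantifying against a
transcript model should supply their own lengths. Coordinates are
stored 1-based inclusive (GFF convention). Vocabulary is fixed across
the package: *expressed* means > 0 in at least one sample;
*well-expressed* means a stage mean above 1 TPM in at least one stage.

## Differential expression

Two external pairwise DE tables are combined by intersection: a gene is
a pairwise DEG only when both tables call it at BH-FDR ≤ 0.01.
Direction is taken from the first table and sign disagreements are
flagged, not fatal. A Welch t-test on log1p values is shipped as a
deliberately simple built-in pairwise test so the synthetic pipeline is
self-contained; it is labelled a stand-in and is not a count model.

The longitudinal screen fits the double-sigmoid impulse
`f(t) = (1/h1)[h0 + (h1−h0)σ(β(t−t1))][h2 + (h1−h2)σ(−β(t−t2))]`
by Gaussian least squares on log1p values, with time as stage rank
0..S−1 (a `time_values` option accepts unequal spacing). Because the
residual sum of squares depends on the data only through the stage
means, fitting uses √n_s-weighted stage means plus the within-stage sum
of squares — exactly equivalent to fitting all replicates and roughly
two orders of magnitude faster. Optimization is a small batched
Levenberg–Marquardt (6 parameters, S residuals) with one deterministic
shape-based start and 9 seeded random restarts; β is optimized on the
log scale within [1e−3, 64], and transition times are clipped to one
span beyond the observed range. The LRT statistic `n·log(RSS0/RSS1)` is
referred to χ² with df = 5 (6-parameter impulse vs 1-parameter
constant). With 5 stages the impulse can approach the saturated
stage-means model, so the χ² reference is approximate; measured type-I
error on 2,000 null negative-binomial genes is ≈ 0.04–0.05 at the 0.05
level (the acceptance script recomputes this). Genes without variance
return p = 1 with a degenerate flag. DE at BH-FDR ≤ 0.05.

PCA centres per gene and decomposes over samples; percent variance
explained is `100·λ_k/Σλ`.

## Single network build

Signed adjacency `((1 + r)/2)^β` with Pearson correlation on log1p
values (biweight midcorrelation is deliberately not implemented; the
Pearson default matches common practice for stage-replicate designs).
TOM is the standard `(Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`.
Modules come from average-linkage clustering of 1 − TOM with a
simplified dynamic cut:

1. candidate partitions are the dendrogram cuts at k = 2..20 clusters,
   scored by mean silhouette width on the dissimilarity;
2. the finest partition scoring at least half the best silhouette is
   chosen. The bias toward fine partitions is intentional: an
   over-split module is healed by the next two steps, whereas two
   modules fused at a coarse cut cannot be separated later;
3. clusters are merged when their eigengene dissimilarity (1 − cor)
   falls below the merge cut height — *before* the size filter, so
   fragments of one true module can clear the minimum size together;
4. clusters below the minimum size are dissolved; their genes are
   re-homed to the nearest retained module only if their mean
   dissimilarity to it is within 1.25× that module's internal mean,
   otherwise they stay unassigned (label 0);
5. a final eigengene-merge pass, then labels are renumbered by
   decreasing size (module 1 = largest).

A dendrogram whose merges are all at one height is a single module only
when the common dissimilarity is small (< 0.5); uniformly distant genes
all stay unassigned. Eigengenes are the first right-singular vector of
the gene-standardized member submatrix, sign-oriented so the mean
correlation with member profiles is positive — this makes merge
decisions deterministic. Connectivity is reported both raw (k_within)
and scaled by module size − 1; cross-network comparisons use the scaled
form because it is size-independent and lives in [0, 1].

## Consensus ensemble

Each run subsamples 80% of genes without replacement and draws one
value per parameter grid uniformly and independently — the
randomization over grids is otherwise unconstrained, so uniform is the
minimal assumption, and every run's draw is logged and replayable. Per-run
seeds are spawned from the master seed, so the whole ensemble is
bit-reproducible. Pairs co-cluster only when both carry a nonzero
module label: unassigned genes never co-cluster. Never-co-sampled pairs
get adjacency 0 rather than missing, with a coverage matrix preserving
the distinction, because downstream matrix algebra needs total
matrices. The consensus network raises the consensus adjacency to
power 6 and clusters its TOM dissimilarity (a `use_tom=False` flag
clusters 1 − adj⁶ directly); minimum module size 30, merge cut 0.25.
The consensus100 filter keeps genes with a covered partner at adjacency
exactly 1 and re-clusters the perfect-agreement edges with the same
power; its default minimum module size is 3, since perfect-agreement
modules are naturally small (median sizes of a few genes).

Full-scale defaults (1000 runs, the full parameter grids) are kept
in `EnsembleConfig`. Desk-scale analyses in the tests and the
acceptance script use 100 runs on 240–600 genes and pass a minimum
module grid of {20, 30, 40}: planted modules hold 80 subsampled genes
at most, so grid values of 60–210 — sized for inputs of tens of
thousands of genes — would leave every cluster below threshold by
construction at this scale. This is a scale adaptation of the same procedure, not a change
to it.

## Tau specificity

`τ = Σ_i (1 − x_i/max x)/(N − 1)` over the focal course's maximal stage
mean plus one atlas's tissue means. With several atlases the default
combines calls with AND (spike-dominant requires τ > 0.9 and a focal
argmax in *every* atlas); a `combine="concat"` mode computes one τ over
the concatenated context vector. Spike-specific is tested as "all
non-focal contexts exactly zero", not floating-point τ = 1. Atlas
tissues overlapping the focal tissue can be excluded by name.

## Enrichment

Exact hypergeometric tails: over-representation is the inclusive upper
tail P(X ≥ k), depletion the inclusive lower tail P(X ≤ k) (the two
share the point mass at k, so p_over + p_under ≥ 1). Family scans flag
raw P < 0.01 by default — no multiple-testing correction, matching the
screening use of these flags — with an optional BH switch. Every scan
records its universe; the default is the genes entering the network.

## CSI

For each child TF, candidate parental sets are all subsets of the other
TFs up to size 2 (including ∅, whose kernel is constant). The
transition model is a GP over parent values at t predicting the child at
t + 1, squared-exponential kernel plus noise. EM alternates the exact
parental-set posterior with an L-BFGS update of kernel hyperparameters
(length-scale, signal variance, noise variance) shared across sets per
child; the per-child evidence is tracked and is non-decreasing by
construction (M-step updates are accepted only on improvement).
Initialization is deterministic — ℓ = 1 on standardized inputs,
σ_f² = 1, σ_n² = 0.1 — so inference is a pure function of the data.
Replicate series are independent realizations of the same transition
function (likelihoods multiply). Edge weight(p→c) = Σ_{Pa∋p} q(Pa) ∈
[0,1]. Depth 2 balances expressiveness against the exponential set
count; desk-scale runs stay at ≤ 30 TFs. Betweenness is directed,
unweighted and unnormalized (a→b→c gives b a score of 1).

## Homoeologs and QTL

"Highly similar expression profiles" is quantified as eigengene
correlation ≥ 0.8 between the two modules; the threshold is a surfaced
parameter, not a claim about the right universal value. Pairs with one
or both genes unassigned fall back to the correlation of the gene
profiles themselves against the same threshold, since grey genes have
no eigengene. Paired t-tests pair replicates by index within each stage;
exactly constant differences give p = NA with a flag. QTL proximity is
nearest-edge inclusive: a gene hits a locus when the locus position (or
interval, in `--interval` mode; BED-like input is otherwise reduced to
its midpoint) is within `window_kbp` of the gene span, distance 0
inside the gene.

## Synthetic generator

Module archetypes are fixed unit-scale 5-stage shapes: vegetative-high
genes falling after the double ridge (down_after_DR), genes rising from
the double ridge onward (up_after_DR), transient peaks at the double
ridge (DR_peak), glume stage (W3.0_peak) and terminal spikelet
(TS_peak), plus flat. Gene g in module m has per-stage log mean
`baseline_g + amplitude·archetype_m + N(0, noise²)` with baseline ~
N(3, 1), amplitude 2.5 and noise sd 0.25; counts are negative binomial
with dispersion 0.1 (typical bulk RNA-seq) around the mean scaled by
gene length. Atlas tables are column-normalized to 10⁶ so they are
magnitude-comparable with focal TPM: broadly expressed genes reach a
sizable share of their focal peak in atlas tissues, spike-dominant
genes sit below 2% of it, spike-specific genes at exactly zero.
Divergent homoeolog partners are re-drawn from a different archetype;
concordant partners copy their partner's archetype with fresh noise.
TF dynamics are linear lag-1 with Gaussian noise; root TFs follow
smooth AR(1) walks.

The up_after_DR and TS_peak archetypes correlate at r ≈ 0.8 by design —
they emulate the genuinely similar "rising" module profiles seen in
spike development — so a clustering at merge cut ≥ 0.18 correctly fuses
them. Recovery fixtures therefore plant the mutually separable triple
{down_after_DR, W3.0_peak, TS_peak} (pairwise r ≤ 0); recovery scores on
fixtures containing both similar shapes measure the merge rule, not the
clustering.

What the generator does not emulate: compositional TPM effects are
present (module peaks shift the per-sample denominator) but library-size
variation, batch effects, gene-length bias within modules, dropout and
the long-tailed module-size distribution of real transcriptomes are
not. Passing recovery tests therefore shows the algorithms recover the
planted statistical structure at realistic noise, not that they would
produce any particular module count on a real tens-of-thousands-of-genes
time course — the full-scale analysis (1000 runs, full grids) is a
cluster-scale recipe.

## Problem sizes

Tests and the acceptance script run at desk scale by choice: 240–600
genes, 5 × 4 samples, 100 ensemble runs, 6 TFs × 20 time points for
CSI, 2,000 null genes for the impulse calibration, 500 homoeolog
pairs. These sizes keep every recovery quantity stable across seeds
while the whole suite completes in about a minute.

## Interfaces

The package is a library: the importable API plus the narrative scripts
in `examples/` are the interface, and `scripts/acceptance.py` is the
reproduction entry point. No shell CLI is shipped — the intended use is
from Python, and a thin CLI would add surface without capability.
Writers (partition, eigengene, pair-counter, edge-table TSV and GraphML
for Cytoscape) emit deterministic column order.
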