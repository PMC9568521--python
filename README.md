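# spikenet

Consensus co-expression and causal networks for temporal spike
transcriptomes.

`spikenet` is a Python library for analysing a developmental RNA-seq
time course of the cereal inflorescence (spike) — the kind of dataset
sampled from the shoot apical meristem across Waddington stages W1
(vegetative meristem), W2 (double ridge), W3.0 (glume primordium),
W3.25 (lemma primordium) and W3.5 (terminal spikelet) with a few
biological replicates per stage. It is written for researchers who want
to go from a count matrix to interpretable network structure: which
gene modules dominate each developmental window, which genes are
expressed nowhere else in the plant, which transcription factors (TFs)
likely drive which, and which homoeolog pairs of a polyploid genome
have diverged in expression.

## What it computes

**Consensus co-expression networks.** A single signed WGCNA-style build
uses the adjacency `a_ij = ((1 + cor_ij)/2)^β`, the topological overlap
measure (TOM), average-linkage clustering with a simplified dynamic
tree cut, eigengene merging and intramodular connectivity
`k_scaled(i) = Σ_{j∈module(i)} a_ij / (|module| − 1)`. The consensus
procedure runs many such builds on random 80% gene subsamples with
parameters drawn from grids (power ∈ {1,2,4,8,12,16,20}, minimum module
size ∈ {40,…,210}, merge cut ∈ {0.15,…,0.3}) and tallies, per gene
pair,

```
adj_ij = (# runs clustering i with j) / (# runs sampling both i and j)
```

The consensus network re-clusters `adj^6`; the *consensus100* network
keeps only genes with a partner at `adj = 1` (perfect agreement across
the ensemble).

**Tissue specificity.** The Tau index over N expression contexts,
`τ = Σ_i (1 − x_i/max(x)) / (N − 1)`, compares the focal course's
maximal stage mean with multi-tissue atlas means: τ > 0.9 with a focal
maximum in every atlas is *spike-dominant*; exactly zero atlas
expression (τ = 1) is *spike-specific*.

**Differential expression.** A consensus-intersection rule over any two
DE tables (Benjamini–Hochberg FDR ≤ 0.01 in both), and a longitudinal
impulse-model test: Gaussian least squares on log1p values of
`f(t) = (1/h1)·[h0 + (h1−h0)σ(β(t−t1))]·[h2 + (h1−h2)σ(−β(t−t2))]`
against a constant model, with a χ²(5) likelihood-ratio p-value and
FDR ≤ 0.05.

**Causal structure inference (CSI).** For each TF a posterior over
candidate parental sets (≤ 2 parents) under a Gaussian-process
transition model; the weight of edge p→c is the marginal posterior
probability that p belongs to c's parental set. Edges are screened at
weight > 0.001 and ≥ 0.03; betweenness centrality flags hub TFs.

**Homoeologs and QTL.** A/B-genome pairs are *same-module*,
*similar-profile* (eigengene correlation ≥ 0.8) or *divergent*, with
per-stage paired t-tests; genes within 500 kbp of mapped yield-QTL
positions are flagged.

**Synthetic data.** A seeded generator plants all of the above —
module archetypes over the 5 stages, negative-binomial counts, TF
labels, atlases with spike-dominant genes, concordant/divergent
homoeolog pairs, and directed TF dynamics — and returns the ground
truth for recovery scoring.

## Worked example

`examples/04_consensus_network.py` plants three module archetypes in a
240-gene, 5-stage × 4-replicate count matrix, runs a 100-build
ensemble, and prints:

```
ensemble: 100 runs; mean co-sampling per pair 63.9
consensus modules: {1: 80, 2: 79, 3: 77}
planted-module ARI, consensus: 0.975
planted-module ARI, standard:  1.0
mean scaled connectivity, consensus vs standard: 0.978 vs 0.191
consensus100: 236 genes in 3 modules
```

The mean co-sampling of 63.9 matches the sampling expectation
`100 · 0.8 · (0.8·240 − 1)/239`. The adjusted Rand index (ARI) of
0.975 says the consensus modules recover the planted ones almost
exactly, and the consensus network's scaled intramodular connectivity
(0.978) sits far above the single standard build's (0.191) — the
consensus procedure concentrates genes into tightly agreeing modules.
The other `examples/` scripts walk the remaining capabilities
(simulation, DE screens, Tau, CSI, homoeologs/QTL) the same way.

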