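"""Seeded synthetic-data generators with planted truth for recovery tests.

The generators emulate the statistical structure of a 5-stage x
4-replicate spike developmental time course: co-expression modules built
from a small set of archetype stage profiles (vegetative-high genes
falling after the double-ridge stage, genes rising after it, transient
double-ridge / glume-stage / terminal-spikelet peaks, and flat genes),
negative-binomial counts, TF family labels, homoeolog pairs (mostly
concordant, a minority planted divergent), multi-tissue atlas tables
with planted spike-dominant and spike-specific genes, QTL loci placed
near known genes, and TF time series driven by planted lag-1 causal
edges.  Every generator is a pure function of (spec, seed); truth labels
are returned alongside the data for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TPM_SCALE, ExpressionMatrix, GeneAnnotation, StageDesign

__all__ = [
    "ARCHETYPES",
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_timecourse",
    "generate_grn_series",
    "generate_qtl_loci",
]

STAGES = ("W1", "W2", "W3.0", "W3.25", "W3.5")

#: unit-scale stage profiles over the 5 stages (qualitative module shapes)
ARCHETYPES: dict[str, tuple] = {
    "down_after_DR": (1.0, 0.9, 0.3, 0.15, 0.1),
    "up_after_DR": (0.1, 0.2, 0.8, 0.9, 1.0),
    "DR_peak": (0.2, 1.0, 0.4, 0.2, 0.2),
    "W3.0_peak": (0.2, 0.4, 1.0, 0.4, 0.2),
    "TS_peak": (0.1, 0.15, 0.3, 0.5, 1.0),
    "flat": (0.5, 0.5, 0.5, 0.5, 0.5),
}

TF_FAMILIES = ("MIKC-MADS", "bHLH", "MYB", "TCP", "RAV", "WOX", "SRS", "GRF", "B3", "SPL")


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the synthetic time course.

    Defaults emulate the sampled design: 5 stages x 4 replicates,
    modules drawn from the archetype shapes, log-normal baselines,
    negative-binomial counts (dispersion 0.1, typical of bulk RNA-seq),
    ~10% TFs, homoeolog pairs about 20% divergent, two atlases of 15 and
    22 tissues, and ~10% spike-dominant genes.
    """

    n_modules: int = 5
    genes_per_module: int = 50
    n_background: int = 0  # extra unplanted (flat, high-noise) genes
    archetypes: tuple = ("down_after_DR", "up_after_DR", "DR_peak", "W3.0_peak", "TS_peak")
    stages: tuple = STAGES
    n_replicates: int = 4
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    amplitude: float = 2.5
    noise_sd: float = 0.25
    nb_dispersion: float = 0.1
    tf_fraction: float = 0.1
    n_homoeolog_pairs: int = 0
    divergent_fraction: float = 0.2
    atlas_tissues: dict = field(default_factory=lambda: {"atlas_a": 15, "atlas_b": 22})
    spike_dominant_fraction: float = 0.1
    spike_specific_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name, frac in (
            ("tf_fraction", self.tf_fraction),
            ("divergent_fraction", self.divergent_fraction),
            ("spike_dominant_fraction", self.spike_dominant_fraction),
            ("spike_specific_fraction", self.spike_specific_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.divergent_fraction > 0 and self.n_homoeolog_pairs == 0 and self.divergent_fraction != 0.2:
            raise ValueError("divergent_fraction set but no homoeolog pairs requested")
        if self.spike_specific_fraction > self.spike_dominant_fraction:
            raise ValueError("spike_specific genes are a subset of spike_dominant genes")
        unknown = set(self.archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")


@dataclass
class SyntheticTruth:
    """Planted labels emitted alongside the synthetic data."""

    modules: pd.Series  # gene -> planted module (0 = background)
    spike_dominant: pd.Series  # bool per gene
    spike_specific: pd.Series
    divergent_pairs: pd.DataFrame  # gene_a, gene_b, divergent flag
    edges: list = field(default_factory=list)  # planted (parent, child, weight)


@dataclass
class SyntheticDataset:
    counts: ExpressionMatrix
    annotation: GeneAnnotation
    atlases: dict
    pairs: pd.DataFrame
    truth: SyntheticTruth


def _archetype_values(name: str, n_stages: int) -> np.ndarray:
    base = np.asarray(ARCHETYPES[name], dtype=float)
    if n_stages == base.size:
        return base
    return np.interp(np.linspace(0, 1, n_stages), np.linspace(0, 1, base.size), base)


def generate_timecourse(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate counts, annotation, atlases, homoeolog pairs and truth.

    Gene g in planted module m has per-stage log mean
    ``baseline_g + amplitude * archetype_m(stage) + N(0, noise_sd^2)``;
    counts are negative binomial around ``exp(log mean) * length/1000``.
    Concordant homoeolog partners copy their A-genome gene's archetype;
    divergent partners are re-drawn from a different archetype.  Atlas
    tissue means stay at baseline scale except for spike-dominant genes
    (near-zero atlas expression) and spike-specific genes (exactly zero).
    """
    r_profile, r_counts, r_annot, r_atlas, r_pairs = [np.random.default_rng(s) for s in np.random.SeedSequence(spec.seed).spawn(5)]

    stages = list(spec.stages)
    S = len(stages)
    design = StageDesign.uniform(stages, spec.n_replicates)

    gene_mods: list[tuple[str, int, str]] = []  # (gene, module, archetype)
    for m in range(spec.n_modules):
        arch = spec.archetypes[m % len(spec.archetypes)]
        for i in range(spec.genes_per_module):
            gene_mods.append((f"GENE{m + 1:02d}.{i + 1:04d}", m + 1, arch))
    for i in range(spec.n_background):
        gene_mods.append((f"GENEBG.{i + 1:04d}", 0, "flat"))

    # planted divergent homoeologs: B-genome partners appended as new genes
    pair_rows = []
    if spec.n_homoeolog_pairs:
        module_genes = [g for g, m, _ in gene_mods if m > 0]
        if spec.n_homoeolog_pairs > len(module_genes):
            raise ValueError("more homoeolog pairs requested than module genes")
        a_genes = r_pairs.choice(module_genes, size=spec.n_homoeolog_pairs, replace=False)
        n_div = int(round(spec.divergent_fraction * spec.n_homoeolog_pairs))
        divergent_flags = np.zeros(spec.n_homoeolog_pairs, dtype=bool)
        divergent_flags[:n_div] = True
        r_pairs.shuffle(divergent_flags)
        lookup = {g: (m, a) for g, m, a in gene_mods}
        for ga, div in zip(a_genes, divergent_flags):
            m, arch = lookup[ga]
            gb = ga.replace("GENE", "GENB")
            if div:
                others = [a for a in spec.archetypes if a != arch]
                arch_b = others[int(r_pairs.integers(len(others)))]
                # divergent partner belongs to the planted module of its new archetype
                mod_b = spec.archetypes.index(arch_b) % spec.n_modules + 1 if arch_b in spec.archetypes else 0
            else:
                arch_b, mod_b = arch, m
            gene_mods.append((gb, mod_b, arch_b))
            pair_rows.append({"gene_a": ga, "gene_b": gb, "divergent": bool(div)})
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "divergent"])

    genes = [g for g, _, _ in gene_mods]
    G = len(genes)
    baseline = spec.baseline_log_mean + spec.baseline_log_sd * r_profile.standard_normal(G)
    log_means = np.empty((G, S))
    for i, (_, _, arch) in enumerate(gene_mods):
        prof = _archetype_values(arch, S)
        log_means[i] = baseline[i] + spec.amplitude * prof + spec.noise_sd * r_profile.standard_normal(S)

    lengths = r_annot.integers(500, 5000, size=G)
    mean_counts = np.exp(np.repeat(log_means, spec.n_replicates, axis=1)) * (lengths[:, None] / 1000.0)
    disp = spec.nb_dispersion
    if disp > 0:
        r_nb = 1.0 / disp
        p_nb = r_nb / (r_nb + mean_counts)
        counts_arr = r_counts.negative_binomial(r_nb, p_nb)
    else:
        counts_arr = r_counts.poisson(mean_counts)

    sample_ids = [f"{s}_r{j + 1}" for s in stages for j in range(spec.n_replicates)]
    meta = pd.DataFrame(
        {"stage": np.repeat(stages, spec.n_replicates),
         "replicate": list(range(1, spec.n_replicates + 1)) * S},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    counts = ExpressionMatrix(pd.DataFrame(counts_arr.astype(float), index=pd.Index(genes, name="gene_id"), columns=sample_ids), meta)

    # annotation: alternate A/B chromosomes, sequential coordinates, TF labels
    n_tf = int(round(spec.tf_fraction * G))
    tf_idx = set(r_annot.choice(G, size=n_tf, replace=False))
    fam = [TF_FAMILIES[int(r_annot.integers(len(TF_FAMILIES)))] if i in tf_idx else None for i in range(G)]
    starts = np.arange(G) * 20000 + 1
    annot = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": genes,
                "chromosome": ["1B" if g.startswith("GENB") else "1A" for g in genes],
                "start": starts,
                "end": starts + lengths - 1,
                "tf_family": fam,
                "confidence": ["high" if r_annot.random() < 0.8 else "low" for _ in genes],
            }
        )
    )

    # spike-dominant / spike-specific planted flags and atlas tables
    n_dom = int(round(spec.spike_dominant_fraction * G))
    n_specific = int(round(spec.spike_specific_fraction * G))
    dom_idx = list(r_atlas.choice(G, size=n_dom, replace=False))
    specific_idx = set(dom_idx[:n_specific])
    dom_set = set(dom_idx)
    # atlas tables are TPM-like: per-tissue expression on the same log scale
    # as the focal course, then column-normalized to 1e6 so they are
    # magnitude-comparable with the focal TPM maxima entering tau
    peak = baseline + spec.amplitude  # log of each gene's focal peak scale
    atlases = {}
    for name, n_tissues in spec.atlas_tissues.items():
        vals = np.empty((G, n_tissues))
        for i in range(G):
            if i in specific_idx:
                vals[i] = 0.0
            elif i in dom_set:
                # near-zero relative to the focal peak: tau stays above 0.9
                vals[i] = np.exp(peak[i]) * r_atlas.uniform(0.001, 0.02, size=n_tissues)
            else:
                # broadly expressed: atlas tissues reach a sizable share of the peak
                vals[i] = np.exp(baseline[i] + spec.amplitude * r_atlas.uniform(0.4, 1.0, size=n_tissues))
        vals = TPM_SCALE * vals / vals.sum(axis=0)
        atlases[name] = pd.DataFrame(vals, index=pd.Index(genes, name="gene_id"),
                                     columns=[f"{name}_tissue{j + 1}" for j in range(n_tissues)])

    truth = SyntheticTruth(
        modules=pd.Series({g: m for g, m, _ in gene_mods}, name="module"),
        spike_dominant=pd.Series([i in dom_set for i in range(G)], index=genes, name="spike_dominant"),
        spike_specific=pd.Series([i in specific_idx for i in range(G)], index=genes, name="spike_specific"),
        divergent_pairs=pairs,
    )
    return SyntheticDataset(counts, annot, atlases, pairs, truth)


def generate_grn_series(
    n_tfs: int = 6,
    edges: list | None = None,
    n_time: int = 20,
    n_series: int = 1,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list]:
    """TF x time series driven by planted lag-1 linear dynamics.

    ``edges`` lists (parent, child, weight) by TF index or name; children
    follow x_c(t+1) = sum_p w_pc x_p(t) + N(0, noise_sd^2); root TFs
    (no parents) follow smooth AR(1) random walks.  Returns one
    standardized TF x time DataFrame per replicate series plus the
    planted edge list with TF names.
    """
    rng = np.random.default_rng(seed)
    tfs = [f"TF{i + 1}" for i in range(n_tfs)]
    name = lambda x: tfs[x] if isinstance(x, (int, np.integer)) else x
    edges = [(name(p), name(c), float(w)) for p, c, w in (edges or [])]
    children = {c for _, c, _ in edges}
    parents_of: dict[str, list[tuple[str, float]]] = {}
    for p, c, w in edges:
        parents_of.setdefault(c, []).append((p, w))
    series = []
    for _ in range(n_series):
        x = np.zeros((n_tfs, n_time))
        x[:, 0] = rng.standard_normal(n_tfs)
        for t in range(1, n_time):
            for i, tf in enumerate(tfs):
                if tf in children:
                    drive = sum(w * x[tfs.index(p), t - 1] for p, w in parents_of[tf])
                    x[i, t] = drive + (noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0)
                else:
                    # smooth random walk for roots
                    x[i, t] = 0.9 * x[i, t - 1] + 0.6 * rng.standard_normal()
        df = pd.DataFrame(x, index=tfs, columns=[f"t{t}" for t in range(n_time)])
        series.append(df)
    return series, edges


def generate_qtl_loci(annotation: GeneAnnotation, n_near: int, n_far: int,
                      window_kbp: float = 500.0, seed: int = 0) -> tuple[pd.DataFrame, set]:
    """QTL locus table with ``n_near`` loci planted inside gene windows.

    Near loci are placed within the window of randomly chosen genes;
    far loci are placed beyond every gene's window on a decoy
    chromosome.  Returns (loci frame, set of genes with a planted
    proximal locus).
    """
    rng = np.random.default_rng(seed)
    t = annotation.table
    chosen = rng.choice(len(t), size=n_near, replace=False)
    rows = []
    near_genes = set()
    traits = ("kernel number per spike", "thousand kernel weight", "spikelet number")
    for i, gi in enumerate(chosen):
        g = t.iloc[gi]
        offset = int(rng.integers(-int(window_kbp * 1000), int(window_kbp * 1000)))
        rows.append({"chromosome": g["chromosome"], "position": max(1, int(g["start"]) + offset),
                     "trait": traits[i % 3]})
        near_genes.add(t.index[gi])
    far_pos = int(t["end"].max()) + int(window_kbp * 1000) * 10
    for j in range(n_far):
        rows.append({"chromosome": "9Z", "position": far_pos + j * 1000, "trait": "other"})
    return pd.DataFrame(rows), near_genes
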