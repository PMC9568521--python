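"""Consensus co-expression networks from a randomized subsampling ensemble.

Many independent network builds are run, each on a random 80% gene
subsample (without replacement) with parameters drawn uniformly from
configured grids.  For every unordered gene pair the ensemble tallies
how often the pair was co-sampled and how often it landed in the same
(assigned) module; the consensus adjacency is the ratio
co_clustered / co_sampled in [0, 1].  The final consensus network
re-clusters this adjacency (raised to a soft-threshold power, default 6,
minimum module size 30); the consensus100 network keeps only genes with
at least one partner of adjacency exactly 1 and re-clusters the
perfect-agreement edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .network import (
    ModulePartition,
    NetworkParams,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    signed_adjacency,
    topological_overlap,
)

__all__ = [
    "EnsembleConfig",
    "ConsensusCounters",
    "ConsensusAdjacency",
    "run_ensemble",
    "consensus_adjacency",
    "build_consensus_network",
    "consensus100_filter",
    "compare_partitions",
]

POWER_GRID = (1, 2, 4, 8, 12, 16, 20)
MIN_MODULE_GRID = (40, 60, 90, 120, 150, 180, 210)
MERGE_CUT_GRID = (0.15, 0.2, 0.25, 0.3)


@dataclass
class EnsembleConfig:
    """Ensemble settings; defaults are the full-scale study conditions.

    1000 runs at an 80% gene subsample with power, minimum module size
    and merge cut height drawn uniformly from the grids.  Desk-scale use
    passes smaller ``n_runs`` and a min-module grid scaled to the
    fixture's planted module size.
    """

    n_runs: int = 1000
    subsample_fraction: float = 0.8
    power_grid: tuple = POWER_GRID
    min_module_grid: tuple = MIN_MODULE_GRID
    merge_cut_grid: tuple = MERGE_CUT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must lie in (0, 1]")
        for g in (self.power_grid, self.min_module_grid, self.merge_cut_grid):
            if len(g) == 0:
                raise ValueError("parameter grids must be non-empty")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class ConsensusCounters:
    """Per-pair co-sampling and co-clustering tallies over the ensemble."""

    gene_ids: list[str]
    co_sampled: np.ndarray  # symmetric int matrix
    co_clustered: np.ndarray
    n_runs: int
    run_log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def validate(self) -> None:
        if (self.co_clustered > self.co_sampled).any():
            raise ValueError("co_clustered exceeds co_sampled")
        if (self.co_sampled > self.n_runs).any():
            raise ValueError("co_sampled exceeds number of runs")


@dataclass
class ConsensusAdjacency:
    """Consensus adjacency = co_clustered / co_sampled, with coverage."""

    gene_ids: list[str]
    adj: np.ndarray
    coverage: np.ndarray


def run_ensemble(em: ExpressionMatrix, config: EnsembleConfig, log_transform: bool = True) -> ConsensusCounters:
    """Run the randomized subsampled ensemble and tally pair counters.

    Each run draws floor(fraction * G) genes without replacement and one
    value from each parameter grid using a child RNG spawned from the
    master seed, builds a signed network on the subsample and clusters
    it.  Pairs sharing a nonzero module label co-cluster; unassigned
    genes never co-cluster.  A degenerate run (clustering failure) is
    logged and contributes to neither counter.
    """
    values = np.log1p(em.values) if log_transform else em.values
    genes = list(values.index)
    G = len(genes)
    n_sub = max(2, int(np.floor(config.subsample_fraction * G)))
    co_sampled = np.zeros((G, G), dtype=np.int32)
    co_clustered = np.zeros((G, G), dtype=np.int32)
    children = np.random.SeedSequence(config.seed).spawn(config.n_runs)
    log_rows = []
    for r in range(config.n_runs):
        rng = np.random.default_rng(children[r])
        idx = np.sort(rng.choice(G, size=n_sub, replace=False))
        params = NetworkParams(
            power=int(rng.choice(config.power_grid)),
            min_module_size=int(rng.choice(config.min_module_grid)),
            merge_cut_height=float(rng.choice(config.merge_cut_grid)),
        )
        ok = True
        try:
            sub = values.iloc[idx]
            a, kept = signed_adjacency(sub, params.power)
            keep_pos = idx[[g in set(kept) for g in sub.index]] if len(kept) != len(idx) else idx
            tom = topological_overlap(a)
            part = detect_modules(1.0 - tom, params, gene_ids=list(kept), expr=sub.loc[kept])
            labels = part.labels.to_numpy()
        except Exception:
            ok = False
        log_rows.append(
            {"run": r, "power": params.power, "min_module_size": params.min_module_size,
             "merge_cut_height": params.merge_cut_height, "ok": ok,
             "n_modules": len(set(labels[labels > 0])) if ok else 0}
        )
        if not ok:
            continue
        co_sampled[np.ix_(idx, idx)] += 1
        for m in set(labels[labels > 0]):
            mem = keep_pos[labels == m]
            co_clustered[np.ix_(mem, mem)] += 1
    np.fill_diagonal(co_sampled, 0)
    np.fill_diagonal(co_clustered, 0)
    counters = ConsensusCounters(genes, co_sampled, co_clustered, config.n_runs, pd.DataFrame(log_rows))
    counters.validate()
    return counters


def consensus_adjacency(counters: ConsensusCounters) -> ConsensusAdjacency:
    """Elementwise co_clustered / co_sampled; never-co-sampled pairs get 0."""
    counters.validate()
    with np.errstate(invalid="ignore", divide="ignore"):
        adj = np.where(counters.co_sampled > 0, counters.co_clustered / np.maximum(counters.co_sampled, 1), 0.0)
    np.fill_diagonal(adj, 0.0)
    return ConsensusAdjacency(counters.gene_ids, adj, counters.co_sampled.copy())


def build_consensus_network(
    cadj: ConsensusAdjacency,
    expr: pd.DataFrame | None = None,
    power: int = 6,
    min_module_size: int = 30,
    merge_cut_height: float = 0.25,
    use_tom: bool = True,
) -> ModulePartition:
    """Cluster the consensus adjacency into the final consensus network.

    The adjacency is raised elementwise to ``power``; by default the TOM
    dissimilarity of that powered adjacency is clustered (``use_tom=False``
    clusters 1 - adj^power directly).  Eigengene merging applies when
    expression is supplied.  Connectivity is computed on the powered
    consensus adjacency.
    """
    a = cadj.adj**power
    np.fill_diagonal(a, 0.0)
    diss = 1.0 - topological_overlap(a) if use_tom else 1.0 - a
    np.fill_diagonal(diss, 0.0)
    params = NetworkParams(power=power, min_module_size=min_module_size, merge_cut_height=merge_cut_height)
    part = detect_modules(diss, params, gene_ids=cadj.gene_ids,
                          expr=expr.loc[cadj.gene_ids] if expr is not None else None)
    part.k_within, part.k_scaled = intramodular_connectivity(a, part)
    if expr is not None:
        eig = {m: module_eigengene(expr.loc[part.members(m)]) for m in part.module_ids}
        part.eigengenes = pd.DataFrame(eig, index=list(expr.columns)).T if eig else None
    return part


def consensus100_filter(
    cadj: ConsensusAdjacency,
    expr: pd.DataFrame | None = None,
    power: int = 6,
    min_module_size: int = 3,
) -> tuple[list[str], ModulePartition]:
    """Perfect-agreement subnetwork: keep genes with a partner at adj = 1.

    A gene is retained when at least one covered partner co-clustered
    with it in every run where both were sampled.  The retained-gene
    adjacency restricted to adj = 1 edges is re-clustered with the same
    soft-threshold power as the main consensus build.  Perfect-agreement
    modules are naturally small (median sizes of a few genes), so the
    default minimum module size here is 3 rather than 30.
    """
    perfect = (cadj.adj >= 1.0) & (cadj.coverage > 0)
    keep = perfect.any(axis=1)
    genes = [g for g, k in zip(cadj.gene_ids, keep) if k]
    if not genes:
        return [], ModulePartition(pd.Series(dtype=int, name="module"))
    sub = perfect[np.ix_(keep, keep)].astype(float)
    a = sub**power  # 0/1 edges: power is a no-op, kept for symmetry with the main build
    diss = 1.0 - topological_overlap(a)
    params = NetworkParams(power=power, min_module_size=min_module_size, merge_cut_height=0.25)
    part = detect_modules(diss, params, gene_ids=genes,
                          expr=expr.loc[genes] if expr is not None else None)
    return genes, part


def compare_partitions(p1: ModulePartition, p2: ModulePartition) -> dict:
    """Module-pair Jaccard overlaps and scaled-connectivity histograms.

    Partitions defined on different gene universes are compared on the
    intersection.  Returns a dict with a (module1 x module2) Jaccard
    DataFrame, 10-bin k_scaled histograms over [0, 1] per network, and
    the mean scaled connectivity of each.
    """
    shared = p1.labels.index.intersection(p2.labels.index)
    l1 = p1.labels.loc[shared]
    l2 = p2.labels.loc[shared]
    jac = pd.DataFrame(index=p1.module_ids, columns=p2.module_ids, dtype=float)
    for m1 in p1.module_ids:
        s1 = set(shared[l1 == m1])
        for m2 in p2.module_ids:
            s2 = set(shared[l2 == m2])
            union = s1 | s2
            jac.loc[m1, m2] = len(s1 & s2) / len(union) if union else 0.0
    bins = np.linspace(0.0, 1.0, 11)
    out = {"jaccard": jac, "bins": bins}
    for name, p in (("network1", p1), ("network2", p2)):
        if p.k_scaled is not None:
            ks = p.k_scaled.to_numpy()
            out[f"{name}_hist"] = np.histogram(ks, bins=bins)[0]
            out[f"{name}_mean_k_scaled"] = float(ks.mean())
    return out
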