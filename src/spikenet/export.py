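"""Tabular and GraphML exports with deterministic column order.

Partitions go out as per-gene TSV (module, connectivity), eigengenes as a
module x sample TSV, ensemble counters as a sparse pair table, and
consensus networks as node/edge TSV plus GraphML loadable in Cytoscape.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import ConsensusAdjacency, ConsensusCounters
from .network import ModulePartition

__all__ = [
    "write_partition",
    "write_eigengenes",
    "write_pair_counters",
    "read_pair_counters",
    "write_consensus_graphml",
    "write_edge_table",
]


def write_partition(partition: ModulePartition, path) -> None:
    out = pd.DataFrame({"module": partition.labels})
    if partition.k_within is not None:
        out["k_within"] = partition.k_within
        out["k_scaled"] = partition.k_scaled
    out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_eigengenes(partition: ModulePartition, path) -> None:
    if partition.eigengenes is None:
        raise ValueError("partition has no eigengenes")
    partition.eigengenes.to_csv(path, sep="\t", index_label="module", float_format="%.17g")


def write_pair_counters(counters: ConsensusCounters, path) -> None:
    """Sparse pair table: one row per co-sampled unordered gene pair."""
    i, j = np.triu_indices(len(counters.gene_ids), k=1)
    mask = counters.co_sampled[i, j] > 0
    genes = np.asarray(counters.gene_ids)
    pd.DataFrame(
        {
            "gene_i": genes[i[mask]],
            "gene_j": genes[j[mask]],
            "co_sampled": counters.co_sampled[i, j][mask],
            "co_clustered": counters.co_clustered[i, j][mask],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pair_counters(path, n_runs: int) -> ConsensusCounters:
    t = pd.read_csv(path, sep="\t")
    genes = sorted(set(t["gene_i"]) | set(t["gene_j"]))
    pos = {g: i for i, g in enumerate(genes)}
    G = len(genes)
    co_s = np.zeros((G, G), dtype=np.int32)
    co_c = np.zeros((G, G), dtype=np.int32)
    for _, row in t.iterrows():
        i, j = pos[row["gene_i"]], pos[row["gene_j"]]
        co_s[i, j] = co_s[j, i] = row["co_sampled"]
        co_c[i, j] = co_c[j, i] = row["co_clustered"]
    return ConsensusCounters(genes, co_s, co_c, n_runs)


def write_edge_table(cadj: ConsensusAdjacency, path, threshold: float = 0.5) -> None:
    """Edge TSV of consensus adjacency values at or above ``threshold``."""
    i, j = np.triu_indices(len(cadj.gene_ids), k=1)
    mask = cadj.adj[i, j] >= threshold
    genes = np.asarray(cadj.gene_ids)
    pd.DataFrame(
        {"gene_i": genes[i[mask]], "gene_j": genes[j[mask]], "adj": cadj.adj[i, j][mask]}
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_consensus_graphml(
    cadj: ConsensusAdjacency, partition: ModulePartition, path, threshold: float = 0.5
) -> None:
    """GraphML with module attributes; edges above an adjacency threshold."""
    g = nx.Graph()
    for gene in cadj.gene_ids:
        g.add_node(gene, module=int(partition.labels.get(gene, 0)))
    i, j = np.triu_indices(len(cadj.gene_ids), k=1)
    mask = cadj.adj[i, j] >= threshold
    genes = np.asarray(cadj.gene_ids)
    for a, b, w in zip(genes[i[mask]], genes[j[mask]], cadj.adj[i, j][mask]):
        g.add_edge(a, b, weight=float(w))
    nx.write_graphml(g, path)
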