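"""Randomized subsampling ensemble, consensus adjacency and consensus100."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spikenet import (
    ConsensusAdjacency,
    ConsensusCounters,
    EnsembleConfig,
    build_consensus_network,
    compare_partitions,
    consensus100_filter,
    consensus_adjacency,
    run_ensemble,
)
from spikenet.network import ModulePartition

from conftest import make_matrix


def _block_matrix(seed=0, block=40, n_blocks=2, samples=20, noise=0.15):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((n_blocks, samples))
    x = np.vstack([base[b] + noise * rng.standard_normal((block, samples)) for b in range(n_blocks)])
    return make_matrix((np.abs(x) + 0.1) * 10, stages=["a", "b"])


SMALL_GRID = dict(power_grid=(2, 6), min_module_grid=(10, 20), merge_cut_grid=(0.2, 0.25))


class TestRunEnsemble:
    def test_ensemble_of_one_full_sample(self):
        em = _block_matrix()
        cfg = EnsembleConfig(n_runs=1, subsample_fraction=1.0, seed=0, **SMALL_GRID)
        counters = run_ensemble(em, cfg)
        off = counters.co_sampled[np.triu_indices(80, 1)]
        assert (off == 1).all()
        # co_clustered matches the single partition of that run
        assert counters.run_log.loc[0, "ok"]
        assert counters.co_clustered.max() <= 1

    def test_perfect_pair_reaches_adjacency_one(self):
        rng = np.random.default_rng(3)
        profile = rng.standard_normal(20)
        x = np.vstack([profile + 0.01 * rng.standard_normal((30, 20)),
                       -profile + 0.01 * rng.standard_normal((30, 20))])
        em = make_matrix(np.abs(x) * 5 + 1, stages=["a", "b"])
        cfg = EnsembleConfig(n_runs=50, seed=1, **SMALL_GRID)
        cadj = consensus_adjacency(run_ensemble(em, cfg))
        # genes 0 and 1 share a module whenever co-sampled
        assert cadj.coverage[0, 1] > 0
        assert cadj.adj[0, 1] == pytest.approx(1.0)

    def test_counter_bounds_invariant(self):
        em = _block_matrix(seed=5)
        cfg = EnsembleConfig(n_runs=25, seed=9, **SMALL_GRID)
        counters = run_ensemble(em, cfg)
        assert (counters.co_clustered <= counters.co_sampled).all()
        assert counters.co_sampled.max() <= 25

    def test_co_sampling_rate_matches_probability_oracle(self):
        # P(pair co-sampled) = (0.8G/G) * (0.8G-1)/(G-1) per run
        em = _block_matrix(seed=2, block=50)
        G = 100
        n_runs = 60
        cfg = EnsembleConfig(n_runs=n_runs, seed=4, **SMALL_GRID)
        counters = run_ensemble(em, cfg)
        n_sub = int(0.8 * G)
        p = (n_sub / G) * ((n_sub - 1) / (G - 1))
        expect = n_runs * p
        off = counters.co_sampled[np.triu_indices(G, 1)]
        sd = np.sqrt(n_runs * p * (1 - p))
        assert abs(off.mean() - expect) < 3 * sd / np.sqrt(off.size) + 0.5

    def test_bit_exact_reproducibility_from_master_seed(self):
        em = _block_matrix(seed=7)
        cfg = EnsembleConfig(n_runs=10, seed=123, **SMALL_GRID)
        c1 = run_ensemble(em, cfg)
        c2 = run_ensemble(em, cfg)
        assert np.array_equal(c1.co_sampled, c2.co_sampled)
        assert np.array_equal(c1.co_clustered, c2.co_clustered)
        assert c1.run_log.equals(c2.run_log)


class TestConsensusAdjacency:
    def _counters(self, co_c, co_s):
        genes = [f"g{i}" for i in range(co_c.shape[0])]
        return ConsensusCounters(genes, co_s, co_c, int(co_s.max()))

    def test_ratio_values(self):
        co_s = np.array([[0, 4], [4, 0]])
        co_c = np.array([[0, 3], [3, 0]])
        cadj = consensus_adjacency(self._counters(co_c, co_s))
        assert cadj.adj[0, 1] == pytest.approx(0.75)

    def test_full_agreement_is_one_and_zero_is_zero(self):
        co_s = np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0]])
        co_c = np.array([[0, 5, 0], [5, 0, 0], [0, 0, 0]])
        cadj = consensus_adjacency(self._counters(co_c, co_s))
        assert cadj.adj[0, 1] == 1.0 and cadj.adj[0, 2] == 0.0

    def test_never_cosampled_pair_zero_with_zero_coverage(self):
        co_s = np.array([[0, 0], [0, 0]])
        co_c = np.zeros_like(co_s)
        cadj = consensus_adjacency(self._counters(co_c, co_s))
        assert cadj.adj[0, 1] == 0.0 and cadj.coverage[0, 1] == 0


def _block_cadj(sizes, adj_value=1.0):
    G = sum(sizes)
    adj = np.zeros((G, G))
    pos = 0
    for s in sizes:
        adj[pos : pos + s, pos : pos + s] = adj_value
        pos += s
    np.fill_diagonal(adj, 0.0)
    genes = [f"g{i}" for i in range(G)]
    return ConsensusAdjacency(genes, adj, np.full((G, G), 10))


class TestBuildConsensusNetwork:
    def test_two_perfect_blocks_recovered_exactly(self):
        cadj = _block_cadj([40, 40])
        part = build_consensus_network(cadj)
        truth = [0] * 40 + [1] * 40
        assert adjusted_rand_score(truth, part.labels) == pytest.approx(1.0)

    def test_uniform_adjacency_single_module(self):
        cadj = _block_cadj([80], adj_value=1.0)
        part = build_consensus_network(cadj)
        assert part.module_sizes() == {1: 80}

    def test_zero_adjacency_all_unassigned(self):
        G = 60
        cadj = ConsensusAdjacency([f"g{i}" for i in range(G)], np.zeros((G, G)), np.full((G, G), 5))
        part = build_consensus_network(cadj)
        assert set(part.labels) == {0}


class TestConsensus100:
    def test_threshold_is_exact_agreement(self):
        adj = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        adj[2, 0] = adj[0, 2] = 0.99  # high but imperfect
        cadj = ConsensusAdjacency(["a", "b", "c"], adj, np.full((3, 3), 5))
        genes, _ = consensus100_filter(cadj)
        assert genes == ["a", "b"]

    def test_perfect_triad_forms_one_module(self):
        cadj = _block_cadj([3, 40], adj_value=1.0)
        # make the 40-block imperfect so only the triad survives
        cadj.adj[3:, 3:] *= 0.9
        genes, part = consensus100_filter(cadj)
        assert len(genes) == 3
        assert part.module_sizes() == {1: 3}

    def test_no_perfect_edges_empty(self):
        cadj = _block_cadj([30], adj_value=0.8)
        genes, part = consensus100_filter(cadj)
        assert genes == [] and len(part.labels) == 0

    def test_retained_genes_subset_of_universe(self):
        cadj = _block_cadj([10, 20], adj_value=1.0)
        genes, _ = consensus100_filter(cadj)
        assert set(genes) <= set(cadj.gene_ids)


class TestExports:
    def test_pair_counter_round_trip(self, tmp_path):
        em = _block_matrix(seed=1, block=15)
        cfg = EnsembleConfig(n_runs=8, seed=2, **SMALL_GRID)
        counters = run_ensemble(em, cfg)
        from spikenet.export import read_pair_counters, write_pair_counters

        path = tmp_path / "pairs.tsv"
        write_pair_counters(counters, path)
        back = read_pair_counters(path, n_runs=8)
        pos = [back.gene_ids.index(g) for g in counters.gene_ids]
        assert np.array_equal(back.co_sampled[np.ix_(pos, pos)], counters.co_sampled)
        assert np.array_equal(back.co_clustered[np.ix_(pos, pos)], counters.co_clustered)

    def test_graphml_and_partition_writers(self, tmp_path):
        import networkx as nx

        from spikenet.export import write_consensus_graphml, write_partition

        cadj = _block_cadj([5, 5])
        part = ModulePartition(pd.Series([1] * 5 + [2] * 5, index=cadj.gene_ids))
        write_consensus_graphml(cadj, part, tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 20  # two 5-cliques
        write_partition(part, tmp_path / "part.tsv")
        back = pd.read_csv(tmp_path / "part.tsv", sep="\t", index_col=0)
        assert back["module"].tolist() == part.labels.tolist()


class TestComparePartitions:
    def test_identical_partitions_diagonal_one(self):
        labels = pd.Series([1] * 30 + [2] * 20, index=[f"g{i}" for i in range(50)])
        out = compare_partitions(ModulePartition(labels), ModulePartition(labels.copy()))
        assert out["jaccard"].loc[1, 1] == 1.0
        assert out["jaccard"].loc[2, 2] == 1.0

    def test_disjoint_modules_zero(self):
        l1 = pd.Series([1] * 10 + [0] * 10, index=range(20))
        l2 = pd.Series([0] * 10 + [1] * 10, index=range(20))
        out = compare_partitions(ModulePartition(l1), ModulePartition(l2))
        assert out["jaccard"].loc[1, 1] == 0.0

    def test_set_arithmetic_hand_case(self):
        # A = genes 0..29, B = genes 15..44 -> 15/45 = 1/3
        l1 = pd.Series([1 if i < 30 else 0 for i in range(60)], index=range(60))
        l2 = pd.Series([1 if 15 <= i < 45 else 0 for i in range(60)], index=range(60))
        out = compare_partitions(ModulePartition(l1), ModulePartition(l2))
        assert out["jaccard"].loc[1, 1] == pytest.approx(1 / 3)
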