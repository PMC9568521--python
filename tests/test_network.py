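"""Signed adjacency, TOM, module detection, eigengenes, connectivity."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from spikenet import (
    ModulePartition,
    NetworkParams,
    build_network,
    counts_to_tpm,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    signed_adjacency,
    topological_overlap,
)
from spikenet.simulate import SyntheticSpec, generate_timecourse

from conftest import SEPARABLE, make_matrix


def _adj_from(x, power):
    return signed_adjacency(pd.DataFrame(np.asarray(x, dtype=float)), power)


class TestSignedAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.vstack([np.arange(10.0), 2 * np.arange(10.0) + 3])
        for beta in (1, 6, 20):
            a, _ = _adj_from(x, beta)
            assert a[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_gives_zero(self):
        x = np.vstack([np.arange(10.0), -np.arange(10.0)])
        a, _ = _adj_from(x, 2)
        assert a[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_three_gene_case(self):
        rng = np.random.default_rng(0)
        x = rng.random((3, 12))
        a, _ = _adj_from(x, 2)
        r = np.corrcoef(x)
        for i in range(3):
            for j in range(i + 1, 3):
                assert a[i, j] == pytest.approx(((1 + r[i, j]) / 2) ** 2)

    def test_zero_variance_gene_removed(self):
        x = np.vstack([np.arange(6.0), np.full(6, 2.0)])
        a, genes = _adj_from(x, 2)
        assert a.shape == (1, 1) and genes == [0]

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_range_and_power_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((15, 10))
        prev = None
        for beta in (1, 2, 4, 8, 20):
            a, _ = _adj_from(x, beta)
            assert np.allclose(a, a.T)
            assert (a >= 0).all() and (a <= 1).all()
            if prev is not None:
                assert (a <= prev + 1e-12).all()
            prev = a


class TestTopologicalOverlap:
    def test_identical_rows_full_overlap(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_no_shared_neighbors_zero(self):
        a = np.zeros((3, 3))
        a[0, 2] = a[2, 0] = 0.0
        assert topological_overlap(a)[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force_triple_sum(self):
        rng = np.random.default_rng(1)
        a = rng.random((4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        k = a.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                shared = sum(a[i, u] * a[u, j] for u in range(4))
                expect = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
                assert tom[i, j] == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((20, 20))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()


def _two_block_frame(seed=0, block=50, samples=20, noise=0.2):
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((2, samples))
    x = np.vstack(
        [base[0] + noise * rng.standard_normal((block, samples)),
         base[1] + noise * rng.standard_normal((block, samples))]
    )
    return pd.DataFrame(x, index=[f"g{i}" for i in range(2 * block)])


class TestDetectModules:
    def test_two_planted_blocks_fully_recovered(self):
        x = _two_block_frame()
        a, genes = signed_adjacency(x, 6)
        part = detect_modules(1 - topological_overlap(a), NetworkParams(power=6, min_module_size=30),
                              gene_ids=genes, expr=x)
        assert len(part.module_ids) == 2
        truth = [0] * 50 + [1] * 50
        assert adjusted_rand_score(truth, part.labels) == pytest.approx(1.0)

    def test_identical_genes_single_module(self):
        x = pd.DataFrame(np.tile(np.random.default_rng(0).standard_normal(20), (40, 1)))
        a, genes = signed_adjacency(x, 6)
        part = detect_modules(1 - topological_overlap(a), NetworkParams(power=6, min_module_size=30))
        assert part.module_sizes() == {1: 40}

    def test_blocks_below_min_size_unassigned(self):
        rng = np.random.default_rng(2)
        x = pd.DataFrame(np.vstack([rng.standard_normal(20) + 0.1 * rng.standard_normal((10, 20))
                                    for _ in range(3)]))
        a, genes = signed_adjacency(x, 6)
        part = detect_modules(1 - topological_overlap(a), NetworkParams(power=6, min_module_size=30))
        assert set(part.labels) == {0}

    def test_fewer_genes_than_min_size(self):
        part = detect_modules(np.zeros((5, 5)), NetworkParams(min_module_size=30))
        assert set(part.labels) == {0}

    def test_gene_order_invariance(self):
        x = _two_block_frame(seed=5)
        perm = np.random.default_rng(9).permutation(len(x))
        xp = x.iloc[perm]
        a1, g1 = signed_adjacency(x, 6)
        p1 = detect_modules(1 - topological_overlap(a1), NetworkParams(power=6, min_module_size=30),
                            gene_ids=g1, expr=x)
        a2, g2 = signed_adjacency(xp, 6)
        p2 = detect_modules(1 - topological_overlap(a2), NetworkParams(power=6, min_module_size=30),
                            gene_ids=g2, expr=xp)
        aligned = p2.labels.loc[p1.labels.index]
        assert adjusted_rand_score(p1.labels, aligned) == pytest.approx(1.0)


class TestModuleEigengene:
    def test_single_gene_module_is_standardized_profile(self):
        x = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
        e = module_eigengene(x)
        z = (x.to_numpy()[0] - 2.5) / x.to_numpy()[0].std()
        assert np.allclose(np.abs(e), np.abs(z / np.linalg.norm(z)))
        assert np.corrcoef(e, z)[0, 1] > 0

    def test_identical_members_common_profile(self):
        profile = np.array([0.0, 1.0, 4.0, 2.0])
        x = pd.DataFrame(np.tile(profile, (6, 1)))
        e = module_eigengene(x)
        assert abs(np.corrcoef(e, profile)[0, 1]) == pytest.approx(1.0)

    def test_matches_brute_force_pca_and_tracks_mean(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(20)
        x = pd.DataFrame(base + 0.2 * rng.standard_normal((5, 20)))
        e = module_eigengene(x)
        # brute-force first PC of standardized genes
        z = (x.to_numpy() - x.to_numpy().mean(1, keepdims=True)) / x.to_numpy().std(1, keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        pc1 = v[:, -1]
        assert abs(np.corrcoef(e, pc1)[0, 1]) == pytest.approx(1.0, abs=1e-8)
        assert np.corrcoef(e, x.mean(axis=0))[0, 1] >= 0.9


class TestIntramodularConnectivity:
    def test_saturated_module_scaled_to_one(self):
        a = np.ones((4, 4)) - np.eye(4)
        part = ModulePartition(pd.Series([1, 1, 1, 1], index=range(4)))
        kw, ks = intramodular_connectivity(a, part)
        assert np.allclose(ks, 1.0)
        assert np.allclose(kw, 3.0)

    def test_singleton_module_zero_by_convention(self):
        a = np.ones((2, 2)) - np.eye(2)
        part = ModulePartition(pd.Series([1, 2], index=range(2)))
        kw, ks = intramodular_connectivity(a, part)
        assert ks.tolist() == [0.0, 0.0]

    def test_hand_three_gene_module(self):
        a = np.array([[0.0, 0.2, 0.7], [0.2, 0.0, 0.4], [0.7, 0.4, 0.0]])
        part = ModulePartition(pd.Series([1, 1, 1], index=range(3)))
        kw, ks = intramodular_connectivity(a, part)
        assert kw.tolist() == pytest.approx([0.9, 0.6, 1.1])
        assert ks.tolist() == pytest.approx([0.45, 0.3, 0.55])

    def test_unassigned_genes_zero(self):
        a = np.ones((3, 3)) - np.eye(3)
        part = ModulePartition(pd.Series([1, 1, 0], index=range(3)))
        _, ks = intramodular_connectivity(a, part)
        assert ks.iloc[2] == 0.0


class TestPlantedRecoverySingleBuild:
    @pytest.mark.parametrize("power", [1, 8, 20])
    @pytest.mark.parametrize("merge_cut", [0.15, 0.3])
    def test_grid_recovery(self, planted_dataset, planted_tpm, power, merge_cut):
        part = build_network(planted_tpm, NetworkParams(power=power, min_module_size=30,
                                                        merge_cut_height=merge_cut))
        truth = planted_dataset.truth.modules.loc[part.gene_ids]
        assert adjusted_rand_score(truth, part.labels) >= 0.9
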