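"""Network construction and module detection tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import panconserve as pc
from panconserve.network import (
    UNASSIGNED,
    adjacency,
    build_cohort_network,
    detect_modules,
    select_soft_threshold,
    tom_similarity,
)
from panconserve.simulate import ExpressionDataset


def _dataset(mat: np.ndarray, prefix: str = "G") -> ExpressionDataset:
    genes = [f"{prefix}{i}" for i in range(mat.shape[0])]
    samples = [f"S{j}" for j in range(mat.shape[1])]
    return ExpressionDataset(cancer="X", expression=pd.DataFrame(mat, index=genes, columns=samples))


class TestAdjacency:
    def test_perfectly_correlated_pair_is_one(self):
        x = np.vstack([np.arange(10.0), 2 * np.arange(10.0) + 3])
        net = adjacency(_dataset(x), power=6)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_halfway_correlation_to_the_sixth_power(self):
        # zero-mean orthogonal u, v of equal norm; cor(u, u/2 + v sqrt(3)/2) = 0.5
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0])
        x = np.vstack([u, 0.5 * u + np.sqrt(0.75) * v])
        net = adjacency(_dataset(x), power=6)
        assert net.adjacency[0, 1] == pytest.approx(0.5**6, rel=1e-9)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((2, 2000))
        net = adjacency(_dataset(x), power=6)
        assert net.adjacency[0, 1] < 1e-4

    def test_entries_bounded_and_symmetric(self, two_cohorts):
        datasets, _, _ = two_cohorts
        net = adjacency(datasets[0], power=6)
        a = net.adjacency
        assert np.all((a >= 0) & (a <= 1))
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)

    def test_signed_mode_maps_anticorrelation_low(self):
        x = np.vstack([np.arange(10.0), -np.arange(10.0)])
        net = adjacency(_dataset(x), power=2, mode="signed")
        assert net.adjacency[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_dropped_with_warning(self):
        x = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.warns(UserWarning, match="constant"):
            net = adjacency(_dataset(x), power=2)
        assert len(net.genes) == 2


class TestSoftThreshold:
    def test_mean_connectivity_decreases_with_power(self, two_cohorts):
        datasets, _, _ = two_cohorts
        _, fit = select_soft_threshold(datasets[0], candidate_powers=[1, 6])
        k = fit.set_index("power")["mean_connectivity"]
        assert k[1] >= k[6]

    def test_planted_fixture_reaches_fit_threshold(self):
        cfg = pc.SimulationConfig(
            n_cancers=1, cancer_names=["A"], samples_per_cancer=[200],
            n_genes=190,
            module_specs=[
                pc.ModuleSpec(size=30, member_cancers=("A",), within_correlation=0.7)
                for _ in range(3)
            ],
            n_background_genes=100, risk_spec=None, seed=7,
        )
        datasets, _, _ = pc.generate_multicancer(cfg)
        chosen, fit = select_soft_threshold(datasets[0], candidate_powers=list(range(1, 13)))
        assert (fit["sft_r2"] >= 0.8).any()
        qualifying = fit.loc[fit["sft_r2"] >= 0.8, "power"]
        assert chosen == int(qualifying.iloc[0])

    def test_two_genes_degenerate_fallback(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning):
            chosen, _ = select_soft_threshold(
                _dataset(rng.standard_normal((2, 30))), candidate_powers=[1, 2]
            )
        assert chosen in (1, 2)


class TestTOM:
    def test_fully_connected_triangle_all_one(self):
        net = pc.NetworkModel(genes=["a", "b", "c"], power=1,
                              adjacency=np.ones((3, 3)))
        tom = tom_similarity(net).tom
        assert np.allclose(tom, 1.0)

    def test_empty_offdiagonal_gives_zero_overlap(self):
        net = pc.NetworkModel(genes=["a", "b", "c"], power=1, adjacency=np.eye(3))
        tom = tom_similarity(net).tom
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(tom[off], 0.0)

    def test_three_node_hand_formula(self):
        a = np.array([[1.0, 0.5, 0.8], [0.5, 1.0, 0.8], [0.8, 0.8, 1.0]])
        net = pc.NetworkModel(genes=["a", "b", "c"], power=1, adjacency=a)
        tom = tom_similarity(net).tom
        # TOM_12 = (a13 a23 + a12) / (min(k1, k2) + 1 - a12) = 1.14 / 1.8
        assert tom[0, 1] == pytest.approx(1.14 / 1.8, rel=1e-12)

    def test_bounds_symmetry_diagonal(self, two_cohort_networks):
        nets, _, _ = two_cohort_networks
        tom = nets["C1"].tom
        assert np.all((tom >= 0) & (tom <= 1))
        assert np.allclose(tom, tom.T)
        assert np.allclose(np.diag(tom), 1.0)

    def test_float32_input_matches_float64(self, two_cohorts):
        datasets, _, _ = two_cohorts
        ds32 = ExpressionDataset(
            cancer="C1",
            expression=datasets[0].expression.astype(np.float32).astype(np.float64),
        )
        n64 = tom_similarity(adjacency(datasets[0], 6))
        n32 = tom_similarity(adjacency(ds32, 6))
        assert np.allclose(n64.tom, n32.tom, atol=1e-5)


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        cfg = pc.SimulationConfig(
            n_cancers=1, cancer_names=["A"], samples_per_cancer=[150],
            n_genes=80,
            module_specs=[
                pc.ModuleSpec(size=30, member_cancers=("A",), within_correlation=0.8),
                pc.ModuleSpec(size=30, member_cancers=("A",), within_correlation=0.8),
            ],
            n_background_genes=20, risk_spec=None, seed=3,
        )
        datasets, _, truth = pc.generate_multicancer(cfg)
        _, assign, _ = build_cohort_network(datasets[0], min_module_size=10)
        assert len(assign.module_names) == 2
        genes = [g for g, m in assign.labels.items() if m != UNASSIGNED]
        ari = adjusted_rand_score(
            [truth.true_module_of_gene[g] for g in genes],
            [assign.labels[g] for g in genes],
        )
        assert ari >= 0.9

    def test_pure_noise_yields_no_modules(self):
        cfg = pc.SimulationConfig(
            n_cancers=1, cancer_names=["A"], samples_per_cancer=[150],
            n_genes=120, module_specs=[], n_background_genes=120,
            risk_spec=None, seed=4,
        )
        datasets, _, _ = pc.generate_multicancer(cfg)
        _, assign, _ = build_cohort_network(datasets[0], min_module_size=30)
        assert assign.module_names == []

    def test_single_block_covering_all_genes(self):
        cfg = pc.SimulationConfig(
            n_cancers=1, cancer_names=["A"], samples_per_cancer=[150],
            n_genes=60,
            module_specs=[
                pc.ModuleSpec(size=60, member_cancers=("A",), within_correlation=0.8)
            ],
            n_background_genes=0, risk_spec=None, seed=3,
        )
        datasets, _, _ = pc.generate_multicancer(cfg)
        _, assign, _ = build_cohort_network(datasets[0], min_module_size=10)
        assert assign.sizes == {"M1": 60}

    @pytest.mark.parametrize("rho", [0.6, 0.8])
    def test_detected_count_equals_planted_count(self, rho):
        cfg = pc.SimulationConfig(
            n_cancers=1, cancer_names=["A"], samples_per_cancer=[120],
            n_genes=200,
            module_specs=[
                pc.ModuleSpec(size=s, member_cancers=("A",), within_correlation=rho)
                for s in (40, 35, 30)
            ],
            n_background_genes=95, risk_spec=None, seed=6,
        )
        datasets, _, _ = pc.generate_multicancer(cfg)
        _, assign, _ = build_cohort_network(datasets[0], min_module_size=30)
        assert len(assign.module_names) == 3

    def test_gene_permutation_equivariance(self, two_cohorts):
        datasets, _, _ = two_cohorts
        ds = datasets[0]
        rng = np.random.default_rng(8)
        perm = rng.permutation(len(ds.genes))
        shuffled = ExpressionDataset(
            cancer="C1", expression=ds.expression.iloc[perm]
        )
        _, a1, _ = build_cohort_network(ds)
        _, a2, _ = build_cohort_network(shuffled)
        assert a1.labels == a2.labels

    def test_min_size_below_three_rejected(self, two_cohort_networks):
        nets, _, _ = two_cohort_networks
        with pytest.raises(ValueError):
            detect_modules(nets["C1"], min_module_size=2)
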