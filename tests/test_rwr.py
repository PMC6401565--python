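import numpy as np
import pytest
import scipy.sparse as sp

from metnetprio.edges import EdgeSet
from metnetprio.hetnet import HeteroNetwork, NetworkError, assemble, build_transition
from metnetprio.rwr import (
    RWRParams,
    SeedError,
    SeedSet,
    build_restart_vector,
    rwr_power,
    rwr_solve_oracle,
)
from metnetprio.synthetic import SyntheticNetConfig, generate_hetnet

from conftest import random_hetnet


def uniform_restart(n):
    return np.full(n, 1.0 / n)


class TestSeedSet:
    def test_no_seeds_rejected(self):
        with pytest.raises(SeedError):
            SeedSet()

    def test_eta_out_of_range(self):
        with pytest.raises(SeedError):
            SeedSet(seed_genes=frozenset({"G1"}), eta_phenotype=1.5)

    def test_from_tsv(self, tmp_path):
        (tmp_path / "seeds.tsv").write_text(
            "gene\tG1\ngene\tG2\nphenotype\tP1\n", encoding="utf-8")
        s = SeedSet.from_tsv(tmp_path / "seeds.tsv", eta_phenotype=0.4)
        assert s.seed_genes == {"G1", "G2"}
        assert s.seed_phenotypes == {"P1"}
        assert s.eta_phenotype == 0.4


class TestRestartVector:
    def net(self):
        return assemble([
            EdgeSet.from_pairs("gg", [(f"G{i}", f"G{i+1}", 0.5) for i in range(1, 7)]),
            EdgeSet.from_pairs("gp", [("G1", "P1", 1.0)]),
            EdgeSet.from_pairs("gm", [("G2", "M1", 0.5)]),
        ])

    def test_single_phenotype_seed_gets_all_mass(self):
        net = self.net()
        p0 = build_restart_vector(net, SeedSet(seed_phenotypes=frozenset({"P1"}),
                                               eta_phenotype=0.3))
        assert p0[net.index_of("P1")] == 1.0
        assert p0.sum() == 1.0

    def test_six_genes_one_phenotype_split(self):
        net = self.net()
        genes = frozenset(f"G{i}" for i in range(1, 7))
        p0 = build_restart_vector(
            net, SeedSet(seed_genes=genes, seed_phenotypes=frozenset({"P1"}),
                         eta_phenotype=0.5))
        assert p0[net.index_of("P1")] == pytest.approx(0.5)
        for g in genes:
            assert p0[net.index_of(g)] == pytest.approx(0.5 / 6)
        assert p0.sum() == pytest.approx(1.0, abs=1e-15)

    def test_genes_only_absorb_phenotype_mass(self):
        net = self.net()
        p0 = build_restart_vector(
            net, SeedSet(seed_genes=frozenset({"G1", "G2"}), eta_phenotype=0.9))
        assert p0[net.index_of("G1")] == pytest.approx(0.5)
        assert p0.sum() == pytest.approx(1.0)

    def test_metabolite_seeds_share_gene_mass(self):
        net = self.net()
        p0 = build_restart_vector(
            net,
            SeedSet(seed_genes=frozenset({"G1"}),
                    seed_metabolites=frozenset({"M1"}),
                    seed_phenotypes=frozenset({"P1"}), eta_phenotype=0.4))
        assert p0[net.index_of("P1")] == pytest.approx(0.4)
        assert p0[net.index_of("G1")] == pytest.approx(0.3)
        assert p0[net.index_of("M1")] == pytest.approx(0.3)

    def test_unknown_seed_named(self):
        net = self.net()
        with pytest.raises(SeedError, match="G999"):
            build_restart_vector(net, SeedSet(seed_genes=frozenset({"G999"})))

    def test_wrong_layer_seed_rejected(self):
        net = self.net()
        with pytest.raises(SeedError):
            build_restart_vector(net, SeedSet(seed_genes=frozenset({"P1"})))


class TestRWRPower:
    def test_beta_one_returns_restart_vector(self, small_model, small_net):
        p0 = uniform_restart(small_net.n_nodes)
        scores, n_iter, converged = rwr_power(small_model, p0, RWRParams(beta=1.0))
        assert n_iter == 1 and converged
        np.testing.assert_array_equal(scores, p0)

    def test_two_node_path_worked_example(self):
        net = assemble([EdgeSet.from_pairs("gg", [("G1", "G2", 1.0)])])
        model = build_transition(net, 0.5)
        p0 = np.zeros(2)
        p0[net.index_of("G1")] = 1.0
        scores, _, converged = rwr_power(model, p0, RWRParams(beta=0.5, tol=1e-14))
        assert converged
        assert scores[net.index_of("G1")] == pytest.approx(2 / 3, abs=1e-10)
        assert scores[net.index_of("G2")] == pytest.approx(1 / 3, abs=1e-10)

    def test_small_beta_approaches_degree_proportions(self, rng):
        # connected single-layer graph, uniform restart, beta -> 0+
        n = 40
        pairs = [(f"G{i:02d}", f"G{(i+1):02d}", 1.0) for i in range(n - 1)]
        pairs += [
            (f"G{i:02d}", f"G{j:02d}", float(rng.uniform(0.2, 1)))
            for i in range(n) for j in range(i + 2, n) if rng.random() < 0.2
        ]
        net = assemble([EdgeSet.from_pairs("gg", pairs)])
        model = build_transition(net, 0.5)
        p0 = uniform_restart(net.n_nodes)
        scores, _, converged = rwr_power(
            model, p0, RWRParams(beta=1e-6, tol=1e-13, max_iter=200_000))
        assert converged
        wdeg = np.asarray(net.adjacency.sum(axis=0)).ravel()
        expected = wdeg / wdeg.sum()
        assert np.abs(scores - expected).max() < 1e-4

    def test_iterates_conserve_probability(self, small_model, small_net):
        # replicate the update step by step and check the sum each iterate
        p0 = uniform_restart(small_net.n_nodes)
        beta = 0.3
        p = p0.copy()
        for _ in range(50):
            dangling_mass = p[small_model.dangling].sum()
            p = (1 - beta) * (small_model.W @ p + dangling_mass * p0) + beta * p0
            assert abs(p.sum() - 1.0) < 1e-12

    def test_monotone_l1_residual(self, small_model, small_net):
        p0 = uniform_restart(small_net.n_nodes)
        beta = 0.4
        p = p0.copy()
        residuals = []
        for _ in range(40):
            p_next = (1 - beta) * (small_model.W @ p) + beta * p0
            residuals.append(np.abs(p_next - p).sum())
            p = p_next
        assert all(r2 <= r1 + 1e-15 for r1, r2 in zip(residuals, residuals[1:]))
        # geometric contraction at factor (1 - beta)
        for r1, r2 in zip(residuals, residuals[1:]):
            assert r2 <= (1 - beta) * r1 + 1e-15

    def test_nonconvergence_warns_not_crashes(self, small_model, small_net):
        p0 = uniform_restart(small_net.n_nodes)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            scores, n_iter, converged = rwr_power(
                small_model, p0, RWRParams(beta=0.1, tol=1e-16, max_iter=3))
        assert n_iter == 3 and not converged

    def test_bad_restart_vector_rejected(self, small_model, small_net):
        with pytest.raises(NetworkError):
            rwr_power(small_model, np.ones(small_net.n_nodes), RWRParams())


class TestOracleEquivalence:
    def test_power_matches_oracle_on_random_instances(self, rng):
        for _ in range(10):
            net = random_hetnet(rng, n_g=25, n_m=15, n_p=8, density=0.15)
            model = build_transition(net, lambda_jump=float(rng.uniform(0, 1)))
            i = rng.integers(net.n_nodes)
            p0 = np.zeros(net.n_nodes)
            p0[i] = 1.0
            beta = float(rng.uniform(0.05, 0.95))
            power, _, _ = rwr_power(model, p0, RWRParams(beta=beta, tol=1e-14, max_iter=5000))
            oracle = rwr_solve_oracle(model, p0, beta)
            assert np.abs(power - oracle).max() < 1e-8

    def test_oracle_beta_one(self, small_model, small_net):
        p0 = uniform_restart(small_net.n_nodes)
        np.testing.assert_array_equal(rwr_solve_oracle(small_model, p0, 1.0), p0)

    def test_oracle_size_guard(self):
        n = 2001
        W = sp.csr_matrix((n, n))
        net_model = type("M", (), {"W": W, "dangling": np.ones(n, dtype=bool)})()
        with pytest.raises(NetworkError, match="2000"):
            rwr_solve_oracle(net_model, np.full(n, 1 / n), 0.5)

    def test_unseeded_component_gets_zero_scores(self):
        net = assemble([
            EdgeSet.from_pairs("gg", [("G1", "G2", 1.0), ("G3", "G4", 1.0)]),
        ])
        model = build_transition(net, 0.5)
        p0 = np.zeros(net.n_nodes)
        p0[net.index_of("G1")] = 1.0
        power, _, _ = rwr_power(model, p0, RWRParams(beta=0.3, tol=1e-14))
        oracle = rwr_solve_oracle(model, p0, 0.3)
        for nid in ("G3", "G4"):
            assert power[net.index_of(nid)] == 0.0
            assert oracle[net.index_of(nid)] == pytest.approx(0.0, abs=1e-12)

    def test_dangling_node_handled_identically(self):
        ids = ("G1", "G2", "G3")
        layers = np.array([0, 0, 0], dtype=np.int8)
        A = sp.csr_matrix(
            (np.array([1.0, 1.0]), (np.array([0, 1]), np.array([1, 0]))), shape=(3, 3))
        net = HeteroNetwork(node_ids=ids, layers=layers, adjacency=A)
        model = build_transition(net, 0.5)
        p0 = np.array([0.5, 0.0, 0.5])  # half the restart mass on the isolated node
        power, _, converged = rwr_power(model, p0, RWRParams(beta=0.3, tol=1e-14))
        oracle = rwr_solve_oracle(model, p0, 0.3)
        assert converged
        assert abs(power.sum() - 1.0) < 1e-12
        assert np.abs(power - oracle).max() < 1e-10


class TestSeedDominance:
    def test_seed_scores_beat_median_nonseed(self):
        cfg = SyntheticNetConfig(n_genes=100, n_metabolites=50, n_phenotypes=20,
                                 rng_seed=17)
        edge_sets, truth = generate_hetnet(cfg)
        net = assemble(edge_sets)
        model = build_transition(net, 0.5)
        seeds = SeedSet(seed_genes=truth.seed_genes,
                        seed_phenotypes=frozenset({truth.disease_phenotype}))
        p0 = build_restart_vector(net, seeds)
        scores, _, _ = rwr_power(model, p0, RWRParams())
        seed_idx = [net.index_of(g) for g in truth.seed_genes]
        nonseed = np.ones(net.n_nodes, dtype=bool)
        for i in seed_idx:
            nonseed[i] = False
        median_nonseed = np.median(scores[nonseed])
        for i in seed_idx:
            assert scores[i] > median_nonseed
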