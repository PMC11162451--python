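import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from voxelprot import network
from voxelprot.errors import InvalidArgumentError, NotFoundError, UndefinedCorrelationError
from voxelprot.synthetic import SimulationConfig, generate_intensity


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    k = a.sum(axis=1) - 1.0
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n=20):
    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    labels = [f"P{i:02d}" for i in range(n)]
    return network.soft_adjacency(pd.DataFrame(r, index=labels, columns=labels), beta=6)


class TestProteinCorrelation:
    def test_identical_and_negated_rows(self):
        base = np.array([1.0, 2.0, 5.0, 3.0])
        m = pd.DataFrame(
            [base, base + 3, 2 * base.mean() - base],
            index=["a", "b", "c"],
            columns=[1, 2, 3, 4],
        )
        r = network.protein_correlation(m)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_bruteforce_pearson(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 17)), index=[f"P{i}" for i in range(50)])
        r = network.protein_correlation(m)
        x = m.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        norm = np.sqrt((xc**2).sum(axis=1))
        expected = (xc @ xc.T) / np.outer(norm, norm)
        assert np.abs(r.to_numpy() - expected).max() < 1e-10

    def test_zero_variance_row_named(self):
        m = pd.DataFrame(
            {"p": [1.0, 1.0, 1.0], "q": [1.0, 2.0, 3.0], "s": [2.0, 1.0, 3.0]}
        ).T
        with pytest.raises(UndefinedCorrelationError) as exc:
            network.protein_correlation(m)
        assert exc.value.label == "p"


class TestSoftAdjacency:
    @pytest.mark.parametrize(
        "r,beta,mode,expected",
        [
            (0.5, 6, "unsigned", 0.015625),
            (-0.5, 6, "unsigned", 0.015625),
            (-1.0, 12, "signed", 0.0),
            (1.0, 12, "signed", 1.0),
        ],
    )
    def test_pointwise(self, r, beta, mode, expected):
        rm = pd.DataFrame([[1.0, r], [r, 1.0]], index=["a", "b"], columns=["a", "b"])
        adj = network.soft_adjacency(rm, beta=beta, mode=mode)
        assert adj.adjacency.loc["a", "b"] == pytest.approx(expected, abs=1e-12)
        assert adj.adjacency.loc["a", "a"] == 1.0

    def test_monotone_in_abs_r(self):
        rs = np.linspace(-1, 1, 21)
        rm = pd.DataFrame(np.eye(len(rs)))
        for beta in (1, 6, 12):
            a = np.abs(rs) ** beta
            order = np.argsort(np.abs(rs), kind="stable")
            assert (np.diff(a[order]) >= -1e-15).all()

    def test_beta_below_one_rejected(self):
        rm = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(InvalidArgumentError):
            network.soft_adjacency(rm, beta=0.5)


class TestTopologicalOverlap:
    def _adj(self, a12, a13, a23):
        a = np.array([[1.0, a12, a13], [a12, 1.0, a23], [a13, a23, 1.0]])
        labels = ["a", "b", "c"]
        adj = network.soft_adjacency(
            pd.DataFrame(np.eye(3), index=labels, columns=labels), beta=1
        )
        adj.adjacency = pd.DataFrame(a, index=labels, columns=labels)
        return adj

    def test_fully_connected_limit(self):
        tom = network.topological_overlap(self._adj(1, 1, 1))
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_manual_three_node_value(self):
        tom = network.topological_overlap(self._adj(1, 1, 0))
        assert tom.loc["b", "c"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_triple_loop(self, rng):
        adj = random_adjacency(rng, n=20)
        tom = network.topological_overlap(adj)
        expected = brute_force_tom(adj.adjacency.to_numpy())
        assert np.abs(tom.to_numpy() - expected).max() < 1e-12
        assert ((tom.to_numpy() >= 0) & (tom.to_numpy() <= 1)).all()


class TestSeedNeighborhood:
    def test_top2_matches_sort_oracle(self):
        labels = ["a", "b", "c", "d"]
        r = pd.DataFrame(
            [
                [1.0, 0.9, 0.2, 0.5],
                [0.9, 1.0, 0.1, 0.3],
                [0.2, 0.1, 1.0, 0.8],
                [0.5, 0.3, 0.8, 1.0],
            ],
            index=labels,
            columns=labels,
        )
        adj = network.soft_adjacency(r, beta=6)
        hood = network.seed_neighborhood(adj, "a", k=2)
        assert list(hood.neighbors.index) == ["b", "d"]

    def test_k_larger_than_matrix(self):
        adj = random_adjacency(np.random.default_rng(0), n=5)
        hood = network.seed_neighborhood(adj, "P00", k=100)
        assert len(hood.neighbors) == 4

    def test_unknown_seed(self):
        adj = random_adjacency(np.random.default_rng(0), n=4)
        with pytest.raises(NotFoundError):
            network.seed_neighborhood(adj, "nope")

    def test_threshold_rule_directions(self):
        adj = random_adjacency(np.random.default_rng(3), n=8)
        ge = network.seed_neighborhood(adj, "P00", threshold=0.01, threshold_direction="ge")
        le = network.seed_neighborhood(adj, "P00", threshold=0.01, threshold_direction="le")
        assert (ge.neighbors >= 0.01).all() and (le.neighbors <= 0.01).all()
        assert set(ge.neighbors.index) | set(le.neighbors.index) == set(adj.proteins) - {"P00"}

    def test_noise_free_module_recovery(self):
        cfg = SimulationConfig(
            seed=7,
            noise_sd=0.0,
            missing_rate=0.0,
            n_modules=2,
            proteins_per_module=10,
            n_background_proteins=30,
            n_core_background=30,
            anti_fraction=0.2,
        )
        m, gt = generate_intensity(cfg)
        # background rows are exactly constant at sigma=0; correlation is
        # only defined on the planted module members
        members = [p for p, mod in gt.protein_module.items() if mod > 0]
        adj = network.soft_adjacency(network.protein_correlation(m.loc[members]), beta=6)
        for seed_protein in ("M1P001", "M2P005"):
            module = gt.protein_module[seed_protein]
            members = set(gt.module_members(module)) - {seed_protein}
            hood = network.seed_neighborhood(adj, seed_protein, k=len(members))
            assert set(hood.neighbors.index) == members

    def test_ranking_invariant_in_beta_unsigned(self, rng):
        adjA = random_adjacency(rng, n=12)
        r = adjA.correlation
        hood6 = network.seed_neighborhood(network.soft_adjacency(r, beta=6), "P00", k=11)
        hood12 = network.seed_neighborhood(network.soft_adjacency(r, beta=12), "P00", k=11)
        assert list(hood6.neighbors.index) == list(hood12.neighbors.index)


class TestInversePartners:
    def test_planted_anticorrelated_member(self):
        cfg = SimulationConfig(
            seed=5,
            noise_sd=0.0,
            missing_rate=0.0,
            n_modules=1,
            proteins_per_module=10,
            n_background_proteins=5,
            n_core_background=5,
            anti_fraction=0.3,
        )
        m, gt = generate_intensity(cfg)
        members = [p for p, mod in gt.protein_module.items() if mod > 0]
        r = network.protein_correlation(m.loc[members])
        anti = {p for p, s in gt.protein_sign.items() if s == -1}
        partners = network.inverse_partners(r, "M1P001", t=0.99)
        assert set(partners.index) == anti
        assert np.allclose(partners.to_numpy(), -1.0)

    def test_threshold_validation(self):
        r = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(InvalidArgumentError):
            network.inverse_partners(r, "a", t=1.5)
        with pytest.raises(NotFoundError):
            network.inverse_partners(r, "zz", t=0.5)

    def test_noisy_recovery(self):
        cfg = SimulationConfig(
            seed=13,
            noise_sd=0.05,
            missing_rate=0.0,
            n_modules=1,
            proteins_per_module=20,
            n_background_proteins=30,
            n_core_background=30,
            anti_fraction=0.3,
        )
        m, gt = generate_intensity(cfg)
        r = network.protein_correlation(m)
        anti = {p for p, s in gt.protein_sign.items() if s == -1}
        partners = set(network.inverse_partners(r, "M1P001", t=0.6).index)
        assert len(partners & anti) / len(anti) >= 0.9


class TestEdgeList:
    def test_threshold_counts(self):
        labels = ["a", "b", "c"]
        a = pd.DataFrame(
            [[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]],
            index=labels,
            columns=labels,
        )
        adj = network.AdjacencyMatrix(adjacency=a, correlation=a, beta=1, mode="unsigned")
        assert len(network.edge_list(adj, t=0.4)) == 2
        assert len(network.edge_list(adj, t=0.0)) == 3  # complete graph
        assert network.edge_list(adj, t=0.95) == []

    def test_edges_ordered_and_weighted(self):
        adj = random_adjacency(np.random.default_rng(2), n=6)
        edges = network.edge_list(adj, t=0.0)
        for a, b, w in edges:
            assert a < b
            assert w == pytest.approx(adj.adjacency.loc[a, b])


class TestDetectModules:
    def test_two_perfect_blocks(self):
        labels = [f"P{i}" for i in range(6)]
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        adj = network.AdjacencyMatrix(
            adjacency=pd.DataFrame(a, index=labels, columns=labels),
            correlation=pd.DataFrame(a, index=labels, columns=labels),
            beta=1,
            mode="unsigned",
        )
        assignment = network.detect_modules(adj, cut_height=0.5)
        labels_by_module = assignment.labels.groupby(assignment.labels).groups
        assert set(map(tuple, [sorted(labels_by_module[k]) for k in labels_by_module])) == {
            ("P0", "P1", "P2"),
            ("P3", "P4", "P5"),
        }

    def test_all_ones_single_module(self):
        labels = ["a", "b", "c"]
        ones = pd.DataFrame(np.ones((3, 3)), index=labels, columns=labels)
        adj = network.AdjacencyMatrix(adjacency=ones, correlation=ones, beta=1, mode="unsigned")
        assignment = network.detect_modules(adj, cut_height=0.5)
        assert set(assignment.labels) == {"1"}

    def test_generator_module_recovery(self):
        cfg = SimulationConfig(
            seed=17,
            noise_sd=0.05,
            missing_rate=0.0,
            n_modules=2,
            proteins_per_module=10,
            n_background_proteins=30,
            n_core_background=30,
            anti_fraction=0.0,
        )
        m, gt = generate_intensity(cfg)
        adj = network.soft_adjacency(network.protein_correlation(m), beta=6)
        assignment = network.detect_modules(adj, cut_height=0.5)
        truth = [gt.protein_module[p] for p in assignment.labels.index]
        predicted = [int(v) for v in assignment.labels]
        assert adjusted_rand_score(truth, predicted) >= 0.9
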