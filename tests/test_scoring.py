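import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netmark.errors import ContractError
from netmark.inference import AssociationNetwork
from netmark.pool import RoughNetwork
from netmark.scoring import (
    CRVTable,
    DifferenceMatrix,
    compute_crv,
    difference_matrix,
    permutation_null,
    significant_proteins,
)


def sym_net(proteins, entries, phenotype="cancer"):
    k = len(proteins)
    m = np.zeros((k, k))
    for (i, j), v in entries.items():
        m[i, j] = m[j, i] = v
    return AssociationNetwork(proteins=proteins, matrix=m, phenotype=phenotype)


def make_rough(d: DifferenceMatrix, extra_edges=()):
    # degree-0 nodes are legitimate inputs for the permutation null, so
    # build the graph holder directly instead of through RoughNetwork's
    # stricter constructor invariants
    g = nx.Graph()
    g.add_nodes_from(d.proteins)
    for i, j in zip(*np.nonzero(np.triu(d.matrix != 0, 1))):
        g.add_edge(d.proteins[i], d.proteins[j])
    for a, b in extra_edges:
        g.add_edge(a, b)
    net = object.__new__(RoughNetwork)
    net.proteins = list(d.proteins)
    net.graph = g
    net.degree_cap = max((deg for _, deg in g.degree), default=0) + 2
    return net


class TestDifferenceMatrix:
    def test_identical_networks_zero(self):
        c = sym_net(["A", "B"], {(0, 1): 0.5})
        n = sym_net(["A", "B"], {(0, 1): 0.5}, "noncancer")
        d = difference_matrix(c, n)
        assert np.count_nonzero(d.matrix) == 0

    def test_subtraction(self):
        c = sym_net(["A", "B"], {(0, 1): 0.6})
        n = sym_net(["A", "B"], {(0, 1): -0.2}, "noncancer")
        d = difference_matrix(c, n)
        assert d.matrix[0, 1] == pytest.approx(0.8)

    def test_mismatched_proteins_rejected(self):
        c = sym_net(["A", "B"], {})
        n = sym_net(["A", "C"], {}, "noncancer")
        with pytest.raises(ContractError, match="C"):
            difference_matrix(c, n)

    def test_symmetry_and_zero_diag_inherited(self):
        rng = np.random.default_rng(0)
        k = 8
        m = rng.normal(size=(k, k))
        m = np.triu(m, 1)
        prots = [f"P{i}" for i in range(k)]
        c = AssociationNetwork(prots, m + m.T, "cancer")
        n = AssociationNetwork(prots, np.zeros((k, k)), "noncancer")
        d = difference_matrix(c, n)
        assert np.array_equal(d.matrix, d.matrix.T)
        assert np.all(np.diag(d.matrix) == 0)


class TestComputeCRV:
    def test_direct_row_sum(self):
        d = DifferenceMatrix(
            proteins=["A", "B", "C"],
            matrix=np.array([[0, 0.5, -0.3], [0.5, 0, 0], [-0.3, 0, 0]]),
        )
        np.testing.assert_allclose(compute_crv(d), [0.8, 0.5, 0.3])

    def test_zero_matrix(self):
        d = DifferenceMatrix(proteins=["A", "B"], matrix=np.zeros((2, 2)))
        np.testing.assert_array_equal(compute_crv(d), [0, 0])

    def test_equals_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            k = 20
            m = np.triu(rng.normal(size=(k, k)), 1)
            m = m + m.T
            d = DifferenceMatrix(proteins=[f"P{i}" for i in range(k)], matrix=m)
            crv = compute_crv(d)
            oracle = np.zeros(k)
            for i in range(k):
                for j in range(k):
                    oracle[i] += abs(m[i, j])
            np.testing.assert_array_equal(crv, oracle)


def diff_from_edges(proteins, edges):
    k = len(proteins)
    m = np.zeros((k, k))
    idx = {p: i for i, p in enumerate(proteins)}
    for (a, b), v in edges.items():
        i, j = idx[a], idx[b]
        m[i, j] = m[j, i] = v
    return DifferenceMatrix(proteins=proteins, matrix=m)


class TestPermutationNull:
    def test_zero_matrix_all_p_one(self):
        prots = [f"P{i}" for i in range(5)]
        d = diff_from_edges(prots, {("P0", "P1"): 0.0})
        net = make_rough(d, extra_edges=[("P0", "P1")])
        t = permutation_null(net, d, n_permutations=50, seed=0)
        assert (t.table["p_value"] == 1.0).all()
        assert not t.table["significant"].any()

    def test_below_resolution_label(self):
        # star structure: observed hub score unreachable by random placement
        prots = [f"P{i:02d}" for i in range(20)]
        edges = {("P00", p): 1.0 for p in prots[1:11]}
        d = diff_from_edges(prots, edges)
        net = make_rough(d)
        t = permutation_null(net, d, n_permutations=50, seed=1)
        hub = t.table.set_index("protein").loc["P00"]
        assert hub["p_label"].startswith("<")
        assert hub["p_value"] == pytest.approx(0.5 / (50 * 20))

    def test_null_mean_matches_closed_form(self):
        # every replicate's node-score mean is exactly 2|E|/K * mean(|d_e|)
        rng = np.random.default_rng(2)
        prots = [f"P{i:02d}" for i in range(12)]
        edges = {}
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.3:
                    edges[(prots[i], prots[j])] = rng.normal()
        d = diff_from_edges(prots, edges)
        net = make_rough(d)
        t = permutation_null(net, d, n_permutations=200, seed=3)
        m = len(edges)
        expected = 2 * m / 12 * np.mean([abs(v) for v in edges.values()])
        assert t.null_mean == pytest.approx(expected, rel=1e-12)

    def test_reproducible_with_seed(self):
        prots = [f"P{i}" for i in range(8)]
        rng = np.random.default_rng(4)
        edges = {(prots[i], prots[i + 1]): rng.normal() for i in range(7)}
        d = diff_from_edges(prots, edges)
        net = make_rough(d)
        t1 = permutation_null(net, d, n_permutations=100, seed=5)
        t2 = permutation_null(net, d, n_permutations=100, seed=5)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_scaling_invariance_of_p_values(self):
        prots = [f"P{i}" for i in range(8)]
        rng = np.random.default_rng(6)
        edges = {(prots[i], prots[i + 1]): rng.normal() for i in range(7)}
        d = diff_from_edges(prots, edges)
        d2 = DifferenceMatrix(proteins=prots, matrix=d.matrix * 2.0)
        net = make_rough(d)
        t1 = permutation_null(net, d, n_permutations=100, seed=7)
        t2 = permutation_null(net, d2, n_permutations=100, seed=7)
        np.testing.assert_array_equal(t1.table["p_value"], t2.table["p_value"])

    def test_invalid_permutation_count(self):
        d = diff_from_edges(["A", "B"], {("A", "B"): 1.0})
        net = make_rough(d)
        with pytest.raises(ContractError):
            permutation_null(net, d, n_permutations=0, seed=0)

    def test_support_outside_network_rejected(self):
        prots = ["A", "B", "C"]
        d = diff_from_edges(prots, {("A", "B"): 1.0, ("B", "C"): 1.0})
        pruned = diff_from_edges(prots, {("A", "B"): 1.0})
        net = make_rough(pruned)
        with pytest.raises(ContractError, match="support"):
            permutation_null(net, d, n_permutations=10, seed=0)

    def test_sorted_by_descending_crv(self):
        prots = [f"P{i}" for i in range(6)]
        rng = np.random.default_rng(8)
        edges = {(prots[i], prots[j]): rng.normal()
                 for i in range(6) for j in range(i + 1, 6) if rng.random() < 0.6}
        d = diff_from_edges(prots, edges)
        t = permutation_null(make_rough(d), d, n_permutations=20, seed=9)
        crvs = t.table["crv"].to_numpy()
        assert np.all(np.diff(crvs) <= 1e-12)


class TestRefitNull:
    def test_runs_and_is_reproducible(self):
        from netmark.expression import CANCER, NONCANCER, znormalize
        from netmark.scoring import refit_permutation_null
        from netmark.synthetic import (
            combine_cohorts,
            generate_network_pair,
            simulate_expression,
        )

        truth = generate_network_pair(12, 20, 0.5, seed=1)
        xc = simulate_expression(truth, CANCER, 40, 0.1, 2)
        xn = simulate_expression(truth, NONCANCER, 40, 0.1, 3)
        x = znormalize(combine_cohorts(xc, xn))
        t1 = refit_permutation_null(truth.rough_true, x, n_permutations=15, seed=4)
        t2 = refit_permutation_null(truth.rough_true, x, n_permutations=15, seed=4)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        assert ((t1.table["p_value"] > 0) & (t1.table["p_value"] <= 1)).all()


class TestSignificantProteins:
    def make_table(self, pvals):
        df = pd.DataFrame(
            {
                "protein": [f"P{i}" for i in range(len(pvals))],
                "crv": np.linspace(5, 1, len(pvals)),
                "p_value": pvals,
                "p_label": [f"{p:g}" for p in pvals],
                "significant": [p <= 0.05 for p in pvals],
            }
        )
        return CRVTable(table=df, n_permutations=100, seed=0)

    def test_all_p_one_gives_empty(self):
        t = self.make_table([1.0, 1.0, 1.0])
        assert len(significant_proteins(t).table) == 0

    def test_boundary_inclusive(self):
        t = self.make_table([0.01, 0.05, 0.2])
        sub = significant_proteins(t)
        assert list(sub.table["protein"]) == ["P0", "P1"]
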