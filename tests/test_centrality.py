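"""Six topological measures against closed forms and brute-force oracles."""

import math

import pytest

from netpharm import PPINetwork, compute_centralities, median_of
from conftest import random_ppi
from oracles import brute_centralities

STAR5 = PPINetwork.from_edges([("C", f"L{i}") for i in range(4)])  # K_{1,4}
TRIANGLE = PPINetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])
PATH3 = PPINetwork.from_edges([("A", "B"), ("B", "C")])


def col(net, measure):
    return compute_centralities(net).values[measure].to_dict()


class TestClosedForms:
    def test_star_center(self):
        table = compute_centralities(STAR5).values
        center = table.loc["C"]
        assert center["dc"] == 4
        assert center["bc"] == 6  # all C(4,2) leaf pairs route through the hub
        assert center["cc"] == 1.0
        assert center["lac"] == 0.0
        assert center["nc"] == 0.0

    def test_star_leaf(self):
        leaf = compute_centralities(STAR5).values.loc["L0"]
        assert leaf["dc"] == 1 and leaf["bc"] == 0.0
        assert leaf["cc"] == pytest.approx(4 / 7)

    def test_triangle_all_nodes(self):
        table = compute_centralities(TRIANGLE).values
        for node in "ABC":
            row = table.loc[node]
            assert row["dc"] == 2 and row["bc"] == 0.0 and row["cc"] == 1.0
            assert row["ec"] == pytest.approx(1 / math.sqrt(3), abs=5e-6)  # 0.57735
            assert row["nc"] == 2.0  # both incident edges have ECC = 1/1
            assert row["lac"] == 1.0

    def test_path_middle_betweenness(self):
        assert col(PATH3, "bc")["B"] == 1.0

    def test_complete_graph_betweenness_zero(self):
        k5 = PPINetwork.from_edges(
            [(f"N{i}", f"N{j}") for i in range(5) for j in range(i + 1, 5)]
        )
        assert all(v == 0.0 for v in col(k5, "bc").values())

    def test_isolated_node_conventions(self):
        net = PPINetwork.from_edges([("A", "B")], extra_nodes=["Z"])
        table = compute_centralities(net).values
        assert table.loc["Z"].tolist() == [0.0] * 6

    def test_empty_graph_is_error(self):
        with pytest.raises(ValueError, match="no nodes"):
            compute_centralities(PPINetwork(frozenset(), frozenset()))


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(12))
    def test_random_graphs_match_brute_force(self, seed):
        n = 6 + (seed * 7) % 25
        p = 0.1 + 0.07 * (seed % 9)
        net = random_ppi(n, p, seed=seed)
        table = compute_centralities(net).values
        oracle = brute_centralities(net.nodes, net.edges)
        for measure, expected in oracle.items():
            for node, val in expected.items():
                assert table.loc[node, measure] == pytest.approx(val, abs=1e-8), (
                    f"{measure}({node}) seed={seed}"
                )

    def test_disconnected_graph_ec_per_component(self):
        net = PPINetwork.from_edges(
            [("A", "B"), ("B", "C"), ("A", "C"), ("X", "Y")]
        )
        table = compute_centralities(net).values
        # each component's vector has unit Euclidean norm
        tri = sum(table.loc[n, "ec"] ** 2 for n in "ABC")
        pair = sum(table.loc[n, "ec"] ** 2 for n in "XY")
        assert tri == pytest.approx(1.0, abs=1e-9)
        assert pair == pytest.approx(1.0, abs=1e-9)

    def test_bipartite_component_converges(self):
        # stars are bipartite: plain adjacency power iteration would oscillate
        table = compute_centralities(STAR5).values
        assert table.loc["C", "ec"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)
        for i in range(4):
            assert table.loc[f"L{i}", "ec"] == pytest.approx(0.5 / math.sqrt(2), abs=1e-9)


class TestInvariants:
    @pytest.mark.parametrize("seed", [101, 102, 103])
    def test_structural_invariants(self, seed):
        net = random_ppi(25, 0.2, seed=seed)
        table = compute_centralities(net).values
        assert table["dc"].sum() == 2 * net.n_edges
        assert ((table >= 0) | table.isna()).all().all()
        assert table["cc"].between(0, 1).all()
        assert (table["nc"] <= table["dc"] + 1e-12).all()
        pos = table["dc"] >= 1
        assert (table.loc[pos, "lac"] <= table.loc[pos, "dc"] - 1 + 1e-12).all()

    def test_permutation_invariance(self):
        net = random_ppi(15, 0.25, seed=55)
        mapping = {n: f"Z{n}" for n in net.nodes}
        relabeled = PPINetwork.from_edges(
            ((mapping[u], mapping[v]) for u, v in net.edges),
            extra_nodes=mapping.values(),
        )
        orig = compute_centralities(net).values
        perm = compute_centralities(relabeled).values
        for node in net.nodes:
            assert perm.loc[mapping[node]].tolist() == pytest.approx(
                orig.loc[node].tolist(), abs=1e-10
            )


class TestMedian:
    @pytest.mark.parametrize(
        "values, expected",
        [([1, 2, 3], 2), ([1, 2, 3, 4], 2.5), ([5], 5), ([2, 1], 1.5)],
    )
    def test_median_conventions(self, values, expected):
        assert median_of(values) == expected

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            median_of([])
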