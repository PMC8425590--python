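import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_graph_net, random_membership
from ppimod.infer import MembershipMatrix
from ppimod.netio import AnnotatedNetwork
from ppimod.score import (
    Path,
    brute_force_score,
    enumerate_paths,
    path_decay,
    path_weight,
    score_pair,
    score_pairs,
)


def uniform_membership(n, K=1):
    return MembershipMatrix(values=np.full((n, K), 1.0 / K))


class TestEnumeratePaths:
    def test_triangle_single_path(self, triangle):
        paths = enumerate_paths(triangle, "a", "b", max_interior=3)
        assert [p.nodes for p in paths] == [(0, 2, 1)]  # a-c-b

    def test_four_cycle_two_paths(self, four_cycle):
        paths = enumerate_paths(four_cycle, "a", "c", max_interior=3)
        assert [p.nodes for p in paths] == [(0, 1, 2), (0, 3, 2)]

    def test_direct_edge_never_returned(self, triangle):
        for p in enumerate_paths(triangle, "a", "b", max_interior=3):
            assert p.n_interior >= 1

    def test_disconnected_empty(self):
        net = AnnotatedNetwork.from_edges(
            [("a", "b")], extra_proteins=["a", "b", "c"]
        )
        assert enumerate_paths(net, "a", "c", max_interior=3) == []

    def test_unknown_protein_errors(self, triangle):
        with pytest.raises(KeyError, match="unknown"):
            enumerate_paths(triangle, "a", "zz", max_interior=3)

    def test_lexicographic_order(self):
        rng = np.random.default_rng(0)
        net = random_graph_net(9, 0.5, rng)
        paths = enumerate_paths(net, 0, 8, max_interior=3)
        seqs = [p.nodes for p in paths]
        assert seqs == sorted(seqs)


class TestPathWeight:
    def test_single_interior(self):
        mm = MembershipMatrix(values=np.array([[1.0, 0.0], [0.5, 0.5], [1.0, 0.0]]))
        assert path_weight(Path((0, 1, 2)), mm, 1) == pytest.approx(0.5)

    def test_product(self):
        mm = MembershipMatrix(
            values=np.array([[1.0, 0.0], [0.5, 0.5], [0.4, 0.6], [1.0, 0.0]])
        )
        assert path_weight(Path((0, 1, 2, 3)), mm, 1) == pytest.approx(0.2)

    def test_identity(self):
        mm = MembershipMatrix(values=np.ones((4, 1)))
        assert path_weight(Path((0, 1, 2, 3)), mm, 1) == 1.0

    def test_empty_interior_gives_one(self):
        mm = MembershipMatrix(values=np.ones((2, 1)))
        assert path_weight(Path((0, 1)), mm, 1) == 1.0


class TestPathDecay:
    def test_linear_values(self):
        assert path_decay(3, 1.0) == 3.0
        assert path_decay(1, 2.0) == 2.0
        assert path_decay(1, 1.0) == 1.0

    def test_exp_mode(self):
        assert path_decay(3, 2.0, mode="exp") == 8.0

    def test_zero_interior_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            path_decay(0, 1.0)


class TestScorePair:
    def test_triangle(self, triangle):
        sp = score_pair(triangle, uniform_membership(3), "a", "b", phi=1.0)
        assert sp.score == pytest.approx(1.0)
        assert sp.n_paths == 1

    def test_four_cycle(self, four_cycle):
        sp = score_pair(four_cycle, uniform_membership(4), "a", "c", phi=1.0)
        assert sp.score == pytest.approx(2.0)
        assert sp.n_paths == 2

    def test_disconnected_zero(self):
        net = AnnotatedNetwork.from_edges(
            [("a", "b")], extra_proteins=["a", "b", "c"]
        )
        sp = score_pair(net, uniform_membership(3), "a", "c")
        assert sp.score == 0.0
        assert sp.n_paths == 0

    def test_k_follows_first_protein(self):
        # path a-z-b; z's membership differs per module, and a and b have
        # different argmax modules, so orientation matters
        net = AnnotatedNetwork.from_edges([("a", "z"), ("z", "b")])
        values = np.array([[0.9, 0.1], [0.1, 0.9], [0.3, 0.7]])  # rows a, b, z
        mm = MembershipMatrix(values=values)
        s_ab = score_pair(net, mm, "a", "b").score
        s_ba = score_pair(net, mm, "b", "a").score
        assert s_ab == pytest.approx(0.3)
        assert s_ba == pytest.approx(0.7)

    def test_batch_matches_single(self, four_cycle):
        mm = uniform_membership(4)
        batch = score_pairs(four_cycle, mm, [("a", "c"), ("b", "d")])
        singles = [score_pair(four_cycle, mm, a, b) for a, b in [("a", "c"), ("b", "d")]]
        assert [s.score for s in batch] == [s.score for s in singles]

    def test_empty_batch(self, four_cycle):
        assert score_pairs(four_cycle, uniform_membership(4), []) == []


class TestOracleEquivalence:
    @pytest.mark.parametrize("phi", [1.0, 2.0])
    @pytest.mark.parametrize("max_interior", [1, 2, 3])
    def test_random_graphs(self, phi, max_interior):
        rng = np.random.default_rng(hash((phi, max_interior)) % 2**32)
        for _ in range(20):
            net = random_graph_net(10, 0.35, rng)
            mm = random_membership(10, 3, rng)
            i, j = rng.choice(10, size=2, replace=False)
            fast = score_pair(net, mm, int(i), int(j), phi, max_interior).score
            slow = brute_force_score(net, mm, int(i), int(j), phi, max_interior)
            assert abs(fast - slow) < 1e-12

    def test_petersen_path_counts(self):
        # K=1, phi=1: score = sum over path lengths of (#paths)/interiors
        g = nx.petersen_graph()
        net = AnnotatedNetwork.from_edges(
            [(f"v{a}", f"v{b}") for a, b in g.edges()]
        )
        mm = uniform_membership(10)
        for i, j in [(0, 1), (0, 2), (0, 4), (1, 3), (2, 5)]:
            counts = {}
            for nodes in nx.all_simple_paths(g, i, j, cutoff=4):
                n_int = len(nodes) - 2
                if n_int >= 1:
                    counts[n_int] = counts.get(n_int, 0) + 1
            expected = sum(c / l for l, c in counts.items())
            got = score_pair(net, mm, f"v{i}", f"v{j}", 1.0, 3).score
            assert got == pytest.approx(expected)

    def test_star_leaf_to_leaf(self):
        net = AnnotatedNetwork.from_edges(
            [("hub", f"leaf{i}") for i in range(4)]
        )
        mm = uniform_membership(5)
        sp = score_pair(net, mm, "leaf0", "leaf1", 1.0, max_interior=1)
        assert sp.n_paths == 1
        assert sp.score == pytest.approx(1.0)


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_phi_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph_net(8, 0.4, rng)
        mm = random_membership(8, 2, rng)
        scores = [score_pair(net, mm, 0, 7, phi, 3).score for phi in (1.0, 1.5, 3.0)]
        assert scores[0] >= scores[1] >= scores[2]

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_cap_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        net = random_graph_net(8, 0.4, rng)
        mm = random_membership(8, 2, rng)
        scores = [score_pair(net, mm, 0, 7, 1.0, cap).score for cap in (1, 2, 3)]
        assert scores[0] <= scores[1] <= scores[2]

    def test_adding_edge_never_loses_paths(self):
        rng = np.random.default_rng(4)
        net = random_graph_net(9, 0.3, rng)
        mm = random_membership(9, 2, rng)
        before = score_pair(net, mm, 0, 8, 1.0, 3).n_paths
        adj = net.adjacency.copy()
        # add the first absent off-diagonal edge not incident to 0 or 8
        for i in range(1, 8):
            for j in range(i + 1, 8):
                if not adj[i, j]:
                    adj[i, j] = adj[j, i] = 1
                    break
            else:
                continue
            break
        bigger = AnnotatedNetwork(
            proteins=net.proteins, adjacency=adj,
            annotations=net.annotations, catalog=net.catalog,
        )
        after = score_pair(bigger, mm, 0, 8, 1.0, 3).n_paths
        assert after >= before

    def test_k1_independent_of_membership_values(self, four_cycle):
        a = score_pair(four_cycle, np.ones((4, 1)), "a", "c").score
        b = score_pair(four_cycle, np.full((4, 1), 1.0), "a", "c").score
        assert a == b == pytest.approx(2.0)


class TestModes:
    def test_lw_total_mode_divides_more(self, four_cycle):
        mm = uniform_membership(4)
        interior = score_pair(four_cycle, mm, "a", "c", lw_mode="interior").score
        total = score_pair(four_cycle, mm, "a", "c", lw_mode="total").score
        assert interior == pytest.approx(2.0)
        assert total == pytest.approx(2.0 / 3.0)  # two paths, |L_w| = 3 each

    def test_exp_decay_mode(self, four_cycle):
        mm = uniform_membership(4)
        sp = score_pair(four_cycle, mm, "a", "c", phi=2.0, decay_mode="exp")
        assert sp.score == pytest.approx(1.0)  # two paths, decay 2^1 each
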