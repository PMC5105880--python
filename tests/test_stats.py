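"""Hypergeometric scoring, BH correction, rankings and node reports."""

import random
from fractions import Fraction
from math import comb, isclose

import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from ctxhub import (
    NetworkError,
    StatError,
    bh_adjust,
    build_network,
    compare_rankings,
    hypergeom_upper_tail,
    node_report,
    rank_hubs,
    score_network,
    score_node,
)
from ctxhub.stats import HubRanking, HubScore
from conftest import context_of


def exact_upper_tail(N, K, n, k):
    """Independent rational-arithmetic oracle for p(X >= k)."""
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, n))


class TestHypergeomUpperTail:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (6, 3, 3, 2, 0.5),
            (10, 4, 3, 2, 1 / 3),
            (6, 3, 3, 1, 0.95),
            (6, 3, 3, 0, 1.0),
            (100, 10, 5, 0, 1.0),
        ],
    )
    def test_enumerated_values(self, N, K, n, k, expected):
        assert isclose(hypergeom_upper_tail(N, K, n, k), expected, rel_tol=1e-12)

    @pytest.mark.parametrize(
        "N,K,n,k,bound",
        [
            (5, 6, 3, 1, "K"),   # K > N
            (5, 3, 6, 1, "n"),   # n > N
            (10, 3, 5, 4, "k"),  # k > min(n, K)
            (10, -1, 5, 0, "K"),
            (10, 3, 5, -1, "k"),
        ],
    )
    def test_invalid_parameters_name_the_bound(self, N, K, n, k, bound):
        with pytest.raises(StatError, match=f"invalid hypergeometric.*{bound}"):
            hypergeom_upper_tail(N, K, n, k)

    def test_strictly_decreasing_in_k(self):
        N, K, n = 40, 12, 15
        values = [hypergeom_upper_tail(N, K, n, k) for k in range(0, min(n, K) + 1)]
        assert values[0] == 1.0
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(0.0 < v <= 1.0 for v in values)

    def test_guaranteed_tail_is_one(self):
        # k below the distribution's support minimum: certain event
        assert hypergeom_upper_tail(10, 8, 9, 7) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_matches_rational_oracle_on_random_small_tuples(self, data):
        N = data.draw(st.integers(1, 40))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(n, K)))
        expected = float(exact_upper_tail(N, K, n, k))
        assert isclose(hypergeom_upper_tail(N, K, n, k), expected, rel_tol=1e-11)

    def test_matches_scipy_survival_function_at_scale(self):
        # independent cross-check against the library implementation
        for N, K, n, k in [(20000, 500, 300, 20), (5000, 120, 400, 25), (1000, 50, 80, 10)]:
            ours = hypergeom_upper_tail(N, K, n, k)
            ref = scipy.stats.hypergeom.sf(k - 1, N, K, n)
            assert isclose(ours, ref, rel_tol=1e-9)


def bh_step_up_oracle(pvals):
    """Textbook step-up, written independently of the implementation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    def test_hand_computed_example(self):
        assert bh_adjust([0.005, 0.01, 0.03, 0.8]) == pytest.approx(
            [0.02, 0.02, 0.04, 0.8], abs=1e-12
        )

    def test_singleton_is_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_fixture_family_caps_at_its_maximum(self):
        adj = bh_adjust([0.5, 0.8, 0.5, 0.8, 0.95, 0.5])
        assert adj == pytest.approx([0.95] * 6, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_domain_p_values_rejected(self, bad):
        with pytest.raises(StatError, match="invalid p-value"):
            bh_adjust([0.2, bad])

    def test_adjusted_at_least_raw_and_order_preserving(self):
        rng = random.Random(7)
        for _ in range(50):
            p = [rng.random() or 0.5 for _ in range(rng.randint(1, 40))]
            adj = bh_adjust(p)
            assert all(a >= r for a, r in zip(adj, p))
            assert all(a <= 1.0 for a in adj)
            assert adj == pytest.approx(bh_step_up_oracle(p), abs=1e-12)


class TestScoreNode:
    @pytest.mark.parametrize(
        "node,n,k,p", [("A", 3, 2, 0.5), ("E", 3, 1, 0.95), ("F", 1, 1, 0.5)]
    )
    def test_fixture_scores(self, toy_db, toy_context_bce, node, n, k, p):
        s = score_node(toy_db, toy_context_bce, node)
        assert (s.n, s.k) == (n, k)
        assert s.p_raw == pytest.approx(p, rel=1e-12)
        assert s.p_adj is None
        assert s.db_degree == s.n

    def test_own_contextual_status_does_not_enter_k(self, toy_db, toy_context_bce):
        # B is contextual but is not its own interactor
        s = score_node(toy_db, toy_context_bce, "B")
        assert (s.n, s.k) == (2, 1)  # interactors {A, C}, only C contextual

    def test_unknown_node(self, toy_db, toy_context_bce):
        with pytest.raises(NetworkError, match="unknown node"):
            score_node(toy_db, toy_context_bce, "Q")


class TestScoreNetwork:
    def test_fixture_composition(self, toy_db, toy_context_bce):
        net = build_network(toy_db, context_of(["B", "C", "E"]))
        scores = score_network(toy_db, net, toy_context_bce)
        assert len(scores) == 6
        by_node = {s.node: s for s in scores}
        a = by_node["A"]
        assert (a.n, a.k) == (3, 2)
        assert a.p_raw == pytest.approx(0.5, rel=1e-12)
        assert a.p_adj == pytest.approx(0.95, rel=1e-12)

    def test_family_size_is_the_network(self, toy_db):
        # one seed (F) with one neighbor (E): m = 2
        cs = context_of(["F"])
        from ctxhub import resolve_context

        net = build_network(toy_db, cs)
        scores = score_network(toy_db, net, resolve_context(context_of(["E"]), toy_db))
        assert {s.node for s in scores} == {"E", "F"}
        # adjustment ran with m = 2, i.e. over exactly this family
        assert bh_adjust([s.p_raw for s in scores]) == [s.p_adj for s in scores]

    def test_score_multiset_independent_of_node_order(self, toy_db, toy_context_bce):
        net1 = build_network(toy_db, context_of(["B", "C", "E"]))
        net2 = build_network(toy_db, context_of(["E", "C", "B"]))
        s1 = score_network(toy_db, net1, toy_context_bce)
        s2 = score_network(toy_db, net2, toy_context_bce)
        assert s1 == s2


def _fixture_scores(toy_db, toy_context_bce):
    net = build_network(toy_db, context_of(["B", "C", "E"]))
    return score_network(toy_db, net, toy_context_bce), net


class TestRankings:
    def test_degree_ranking_top3_is_the_degree3_triple(self, toy_db, toy_context_bce):
        scores, _ = _fixture_scores(toy_db, toy_context_bce)
        ranking = rank_hubs(scores, "degree", top=3)
        assert set(ranking.top_nodes()) == {"A", "C", "E"}
        degrees = [s.db_degree for s in ranking.ordered]
        assert degrees == sorted(degrees, reverse=True)

    def test_contextual_top1_has_smallest_p_adj(self):
        scores = [
            HubScore("X", 5, 1, 0.6, 0.9),
            HubScore("Y", 5, 4, 0.001, 0.003),
            HubScore("Z", 5, 2, 0.2, 0.3),
        ]
        assert rank_hubs(scores, "contextual", top=1).top_nodes() == ["Y"]

    def test_top_larger_than_family_returns_all_without_padding(self, toy_db, toy_context_bce):
        scores, _ = _fixture_scores(toy_db, toy_context_bce)
        ranking = rank_hubs(scores, "contextual", top=50)
        assert len(ranking.top_list) == 6

    def test_contextual_tie_breaks_are_deterministic(self, toy_db, toy_context_bce):
        scores, _ = _fixture_scores(toy_db, toy_context_bce)
        r1 = rank_hubs(scores, "contextual", top=6)
        r2 = rank_hubs(list(reversed(scores)), "contextual", top=6)
        assert r1.top_nodes() == r2.top_nodes()
        # all p_adj tie at 0.95; raw p then separates {A,C,F} < {B,D} < E
        assert set(r1.top_nodes()[:3]) == {"A", "C", "F"}
        assert set(r1.top_nodes()[3:5]) == {"B", "D"}
        assert r1.top_nodes()[5] == "E"

    def test_invalid_criterion(self, toy_db, toy_context_bce):
        scores, _ = _fixture_scores(toy_db, toy_context_bce)
        with pytest.raises(StatError, match="invalid criterion"):
            rank_hubs(scores, "betweenness")


class TestCompareRankings:
    def _ranking(self, nodes, criterion="contextual", top=None):
        scores = tuple(
            HubScore(v, 5, 1, 0.5, 0.5) for v in nodes
        )
        return HubRanking(ordered=scores, criterion=criterion, top=top or len(nodes))

    def test_identical_rankings(self):
        a = self._ranking(["X", "Y", "Z"])
        assert compare_rankings(a, a).jaccard == 1.0

    def test_disjoint_top_lists(self):
        cmp = compare_rankings(self._ranking(["X", "Y"]), self._ranking(["P", "Q"]))
        assert cmp.shared == frozenset()
        assert cmp.jaccard == 0.0

    def test_one_shared_of_five(self):
        cmp = compare_rankings(
            self._ranking(["A", "B", "C"]), self._ranking(["C", "D", "E"])
        )
        assert cmp.shared == frozenset({"C"})
        assert cmp.jaccard == pytest.approx(0.2)


class TestNodeReport:
    def test_interactors_contextual_first(self, toy_db, toy_context_bce):
        scores, net = _fixture_scores(toy_db, toy_context_bce)
        rep = node_report(toy_db, scores, net, toy_context_bce, "A")
        assert [r[0] for r in rep.interactors] == ["B", "C", "D"]
        assert [r[1] for r in rep.interactors] == [True, True, False]
        assert all(r[2] for r in rep.interactors)  # all inside the network
        assert sum(r[1] for r in rep.interactors) == 2  # matches k of A

    def test_leaf_node(self, toy_db, toy_context_bce):
        scores, net = _fixture_scores(toy_db, toy_context_bce)
        rep = node_report(toy_db, scores, net, toy_context_bce, "F")
        assert rep.interactors == (("E", True, True),)

    def test_unscored_node_is_an_error(self, toy_db, toy_context_bce):
        scores, net = _fixture_scores(toy_db, toy_context_bce)
        with pytest.raises(NetworkError, match="node not in network"):
            node_report(toy_db, scores, net, toy_context_bce, "Q")
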