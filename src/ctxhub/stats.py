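"""Contextual-hub statistics.

The core test: for each node of the constructed network, the probability
that it has ``k`` or more contextual interactors among its ``n``
database interactors, under random drawing without replacement from a
background of ``N`` interacting genes of which ``K`` are contextual,

    p(X >= k) = sum_{x=k}^{min(n,K)} C(K,x) C(N-K, n-x) / C(N,n)

i.e. the hypergeometric upper tail.  ``n`` is the node's degree in the
FULL filtered database (not inside the constructed network), consistent
with the database-wide background (N, K) and with the degree used for
conventional hub ranking.  Raw p-values are corrected across the network
node family with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import exp, fsum, lgamma
from typing import Sequence

from statsmodels.stats.multitest import multipletests

from .database import InteractionDatabase, background_size
from .errors import NetworkError, StatError
from .network import ContextNetwork, ContextSet


@dataclass(frozen=True)
class HubScore:
    """Per-node enrichment record.

    ``n`` is the count of distinct database interactors (self excluded);
    ``k`` of those are contextual; ``db_degree`` aliases ``n`` in its
    degree-ranking role.  The node's own contextual status never enters
    its score — a node is not its own interactor.
    """

    node: str
    n: int
    k: int
    p_raw: float
    p_adj: float | None = None

    @property
    def db_degree(self) -> int:
        return self.n


@dataclass(frozen=True)
class HubRanking:
    """Deterministically ordered scores under one criterion.

    ``criterion`` is ``"contextual"`` (ascending adjusted p-value) or
    ``"degree"`` (descending database degree); ``top_list`` holds the
    first ``min(top, len(ordered))`` entries.
    """

    ordered: tuple[HubScore, ...]
    criterion: str
    top: int = 20

    @property
    def top_list(self) -> tuple[HubScore, ...]:
        return self.ordered[: self.top]

    def top_nodes(self) -> list[str]:
        return [s.node for s in self.top_list]


@dataclass(frozen=True)
class RankingComparison:
    """Overlap between two top lists (the contextual-vs-degree contrast)."""

    shared: frozenset[str]
    jaccard: float
    top_a: tuple[str, ...]
    top_b: tuple[str, ...]


@dataclass(frozen=True)
class NodeReport:
    """Node-analyzer view: one node and all its database interactors."""

    node: str
    p_adj: float | None
    interactors: tuple[tuple[str, bool, bool], ...]  # (id, contextual, in_network)


def _log_binom(n: int, r: int) -> float:
    return lgamma(n + 1) - lgamma(r + 1) - lgamma(n - r + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail probability ``p(X >= k)`` of Hypergeom(N, K, n).

    Summed in log-space from the largest term downward for numerical
    stability; the result is capped at 1.0 to absorb rounding.

    Raises :class:`StatError` naming the violated bound when the
    parameters are inconsistent.
    """
    if not 0 <= K <= N:
        raise StatError(f"invalid hypergeometric parameters: need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise StatError(f"invalid hypergeometric parameters: need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise StatError(
            f"invalid hypergeometric parameters: need 0 <= k <= min(n, K), "
            f"got k={k}, n={n}, K={K}"
        )
    if k <= max(0, n + K - N):
        return 1.0
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, x) + _log_binom(N - K, n - x) - log_denom
        for x in range(k, min(n, K) + 1)
    ]
    m = max(log_terms)
    # largest contributions first keeps the compensated sum tight
    total = fsum(exp(t - m) for t in sorted(log_terms, reverse=True))
    return min(1.0, exp(m) * total)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Standard step-up: on the ascending sort, ``adj_(i) = min_{j>=i}
    p_(j) * m / j`` capped at 1, mapped back to input positions.
    """
    if len(p_values) == 0:
        raise StatError("invalid p-value: empty family")
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise StatError(f"invalid p-value: {p!r} outside (0, 1]")
    return [float(p) for p in multipletests(list(p_values), method="fdr_bh")[1]]


def score_node(
    db: InteractionDatabase, context: ContextSet, node: str
) -> HubScore:
    """Raw enrichment score for one database node (p_adj left unset)."""
    if node not in db:
        raise NetworkError(f"unknown node: {node}")
    interactors = db.neighbors(node)
    n = len(interactors)
    k = len(interactors & context.contextual)
    p = hypergeom_upper_tail(background_size(db), context.K, n, k)
    return HubScore(node=node, n=n, k=k, p_raw=p)


def score_network(
    db: InteractionDatabase, net: ContextNetwork, context: ContextSet
) -> list[HubScore]:
    """Score every network node and BH-adjust over exactly that family.

    The multiple-testing family is the set of nodes actually tested —
    the constructed network — so ``m`` equals the network size.
    Returned sorted by node ID.
    """
    if context.K < 1:
        raise StatError("invalid p-value family: K = 0")
    nodes = sorted(net.nodes)
    if not nodes:
        raise NetworkError("empty network")
    raw = [score_node(db, context, v) for v in nodes]
    adjusted = bh_adjust([s.p_raw for s in raw])
    return [replace(s, p_adj=a) for s, a in zip(raw, adjusted)]


def _contextual_key(s: HubScore):
    return (s.p_adj, s.p_raw, -s.k, -s.db_degree, s.node)


def _degree_key(s: HubScore):
    return (-s.db_degree, s.p_adj, s.node)


def rank_hubs(
    scores: Sequence[HubScore], criterion: str, top: int = 20
) -> HubRanking:
    """Order scores under one hub criterion.

    ``contextual``: ascending adjusted p-value, ties broken by raw
    p-value, then larger ``k``, then larger degree, then node ID.
    ``degree``: descending database degree, ties by adjusted p-value,
    then node ID.  The chains are fixed so rankings are byte-identical
    across runs and platforms.
    """
    if not scores:
        raise StatError("cannot rank an empty score list")
    if top < 1:
        raise StatError(f"top must be >= 1, got {top}")
    if criterion == "contextual":
        ordered = tuple(sorted(scores, key=_contextual_key))
    elif criterion == "degree":
        ordered = tuple(sorted(scores, key=_degree_key))
    else:
        raise StatError(f"invalid criterion: {criterion!r}")
    return HubRanking(ordered=ordered, criterion=criterion, top=top)


def compare_rankings(a: HubRanking, b: HubRanking) -> RankingComparison:
    """Overlap of two top lists: shared node set and Jaccard index."""
    top_a, top_b = set(a.top_nodes()), set(b.top_nodes())
    union = top_a | top_b
    shared = top_a & top_b
    jaccard = len(shared) / len(union) if union else 1.0
    return RankingComparison(
        shared=frozenset(shared),
        jaccard=jaccard,
        top_a=tuple(a.top_nodes()),
        top_b=tuple(b.top_nodes()),
    )


def node_report(
    db: InteractionDatabase,
    scores: Sequence[HubScore],
    net: ContextNetwork,
    context: ContextSet,
    node: str,
) -> NodeReport:
    """Node-analyzer table: each database interactor of ``node`` with its
    contextual flag and whether it lies inside the constructed network;
    contextual interactors listed first, then lexicographic."""
    by_node = {s.node: s for s in scores}
    if node not in by_node:
        raise NetworkError(f"node not in network: {node}")
    rows = [
        (v, v in context.contextual, v in net.nodes)
        for v in db.neighbors(node)
    ]
    rows.sort(key=lambda r: (not r[1], r[0]))
    return NodeReport(node=node, p_adj=by_node[node].p_adj, interactors=tuple(rows))
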