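"""Contextual gene input and first-neighbor network construction.

The user supplies a gene table (CSV/TSV: one ID column plus numeric or
categorical attributes) and a predicate saying which rows are
"contextual" (e.g. fold-change > 2).  Every uploaded gene found in the
database seeds the network; the predicate controls only contextual
status.  The network is the seeds plus all their first neighbors.
Edges touching a seed are display edges; edges between first neighbors
are kept for the analysis but partitioned separately, mirroring the
convention of hiding neighbor-neighbor edges in visualizations.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import IO

import networkx as nx

from .database import InteractionDatabase, normalize_id
from .errors import ContextError, NetworkError

log = logging.getLogger(__name__)

Edge = tuple[str, str]

_NUMERIC_OPS = {
    "gt": lambda v, t: v > t,
    "ge": lambda v, t: v >= t,
    "lt": lambda v, t: v < t,
    "le": lambda v, t: v <= t,
}


@dataclass(frozen=True)
class Predicate:
    """Contextual-status rule over one attribute column.

    ``op`` is one of ``gt ge lt le eq in``; ``eq`` compares numerically
    when both sides parse as numbers, else as strings; ``in`` tests
    membership in a value set.  ``Predicate.all_rows()`` marks every
    listed gene contextual (the common use case where the uploaded list
    is itself the contextual set).
    """

    attribute: str | None
    op: str | None = None
    value: float | str | frozenset[str] | None = None

    @classmethod
    def all_rows(cls) -> "Predicate":
        return cls(attribute=None)

    @property
    def is_all(self) -> bool:
        return self.attribute is None

    @classmethod
    def parse(cls, text: str) -> "Predicate":
        """Parse ``"logFC gt 2.0"``, ``"group in A,B"`` or ``"all"``."""
        text = text.strip()
        if text.lower() == "all":
            return cls.all_rows()
        parts = text.split(None, 2)
        if len(parts) != 3:
            raise ContextError(
                f"cannot parse predicate {text!r}: expected 'ATTR OP VALUE' or 'all'"
            )
        attr, op, raw = parts
        op = op.lower()
        if op in _NUMERIC_OPS:
            try:
                return cls(attr, op, float(raw))
            except ValueError:
                raise ContextError(
                    f"unparseable attribute value: {raw!r} is not numeric"
                ) from None
        if op == "eq":
            return cls(attr, "eq", raw)
        if op == "in":
            return cls(attr, "in", frozenset(v.strip() for v in raw.split(",")))
        raise ContextError(f"unknown comparator {op!r}")

    def evaluate(self, attributes: dict[str, str], row_label: str) -> bool:
        if self.is_all:
            return True
        if self.attribute not in attributes:
            raise ContextError(f"attribute not found: {self.attribute!r}")
        raw = attributes[self.attribute]
        if self.op in _NUMERIC_OPS:
            try:
                v = float(raw)
            except ValueError:
                raise ContextError(
                    f"unparseable attribute value {raw!r} for gene {row_label}"
                ) from None
            return _NUMERIC_OPS[self.op](v, self.value)
        if self.op == "eq":
            try:
                return float(raw) == float(self.value)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                return raw == self.value
        if self.op == "in":
            return raw in self.value  # type: ignore[operator]
        raise ContextError(f"unknown comparator {self.op!r}")


@dataclass
class ContextInput:
    """Parsed user gene table: ordered rows of (normalized ID, attributes)."""

    rows: list[tuple[str, dict[str, str]]]
    predicate: Predicate

    def eligible(self) -> list[str]:
        """Gene IDs passing the contextual predicate, input order preserved."""
        return [g for g, attrs in self.rows if self.predicate.evaluate(attrs, g)]

    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.rows]


@dataclass
class ContextSet:
    """Contextual genes resolved against the database background.

    ``K`` counts contextually relevant genes with at least one
    interaction in the database queried; eligible genes absent from the
    database are listed in ``missing`` (input order) and excluded from
    the statistic.
    """

    contextual: set[str]
    missing: list[str]

    @property
    def K(self) -> int:
        return len(self.contextual)


@dataclass
class ContextNetwork:
    """Seeds plus first neighbors, with the display/analysis edge split.

    ``display_edges`` have at least one seed endpoint (seed-seed and
    seed-neighbor); ``hidden_edges`` run between first neighbors only.
    Both partitions enter the statistical analysis.
    """

    seeds: set[str]
    neighbors: set[str]
    display_edges: set[Edge]
    hidden_edges: set[Edge]

    @property
    def nodes(self) -> set[str]:
        return self.seeds | self.neighbors

    def role(self, node: str) -> str:
        if node in self.seeds:
            return "seed"
        if node in self.neighbors:
            return "neighbor"
        raise NetworkError(f"node not in network: {node}")


def _sniff_delimiter(header: str) -> str:
    # comma vs tab, decided on the header row
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return "\t"


def parse_context_table(
    stream: IO[str], id_column: str, predicate: Predicate
) -> ContextInput:
    """Parse the user's CSV or TSV gene table.

    The delimiter is auto-detected from the header row.  Gene IDs are
    normalized; duplicate IDs collapse to the first occurrence with a
    logged warning.  Attribute names the predicate references must exist
    in the header.
    """
    first = stream.readline()
    if not first.strip():
        raise ContextError("context table is empty")
    delim = _sniff_delimiter(first)
    reader = csv.DictReader(stream, fieldnames=None, delimiter=delim)
    reader.fieldnames = [c.strip() for c in first.rstrip("\n").split(delim)]
    if id_column not in reader.fieldnames:
        raise ContextError(f"column not found: {id_column!r}")
    if not predicate.is_all and predicate.attribute not in reader.fieldnames:
        raise ContextError(f"attribute not found: {predicate.attribute!r}")
    rows: list[tuple[str, dict[str, str]]] = []
    seen: set[str] = set()
    n_dup = 0
    for row in reader:
        raw_id = (row.get(id_column) or "").strip()
        if not raw_id:
            continue
        gene = normalize_id(raw_id)
        if gene in seen:
            n_dup += 1
            continue
        seen.add(gene)
        attrs = {
            k: (v or "").strip() for k, v in row.items() if k is not None and k != id_column
        }
        rows.append((gene, attrs))
    if not rows:
        raise ContextError("context table has no data rows")
    if n_dup:
        log.warning("collapsed %d duplicate gene ID(s) to first occurrence", n_dup)
    # surface attribute errors eagerly, naming the offending row
    for gene, attrs in rows:
        predicate.evaluate(attrs, gene)
    return ContextInput(rows=rows, predicate=predicate)


def resolve_context(context: ContextInput, db: InteractionDatabase) -> ContextSet:
    """Split predicate-eligible genes into in-database and missing.

    Raises :class:`ContextError` when no eligible gene has a database
    interaction (the enrichment statistic is undefined at K = 0).
    """
    eligible = context.eligible()
    contextual = {g for g in eligible if g in db}
    missing = [g for g in eligible if g not in db]
    if not contextual:
        raise ContextError("no contextual genes in database")
    if missing:
        log.info("%d contextual gene(s) absent from the database", len(missing))
    return ContextSet(contextual=contextual, missing=missing)


def _pair(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def build_network(db: InteractionDatabase, context: ContextInput) -> ContextNetwork:
    """Expand the uploaded gene list to its first-neighbor network.

    All uploaded genes present in the database seed the network,
    contextual or not.  Neighbors are the union of the seeds' database
    interactors minus the seeds themselves.  Every database edge
    internal to the network lands in exactly one partition: display
    (>=1 seed endpoint) or hidden (neighbor-neighbor).
    """
    seeds = {g for g in context.gene_ids() if g in db}
    if not seeds:
        raise NetworkError("no seed genes found in database")
    neighbors: set[str] = set()
    for s in seeds:
        neighbors |= db.neighbors(s)
    neighbors -= seeds
    display: set[Edge] = set()
    for s in seeds:
        for other in db.neighbors(s):
            display.add(_pair(s, other))
    hidden: set[Edge] = set()
    for v in neighbors:
        for other in db.neighbors(v):
            if other in neighbors and v < other:
                hidden.add((v, other))
    return ContextNetwork(
        seeds=seeds, neighbors=neighbors, display_edges=display, hidden_edges=hidden
    )


def write_sif(net: ContextNetwork, stream: IO[str], relation: str = "pp") -> None:
    """Write display edges in simple interaction format (id, relation, id)."""
    for a, b in sorted(net.display_edges):
        stream.write(f"{a}\t{relation}\t{b}\n")


def to_graphml_graph(net: ContextNetwork, context_set: ContextSet) -> nx.Graph:
    """Full network (display + hidden edges) as an attributed graph.

    Node attributes: ``role`` (seed/neighbor) and ``contextual``; edge
    attribute ``displayed`` marks the display partition.
    """
    g = nx.Graph()
    for node in sorted(net.nodes):
        g.add_node(
            node, role=net.role(node), contextual=node in context_set.contextual
        )
    for a, b in sorted(net.display_edges):
        g.add_edge(a, b, displayed=True)
    for a, b in sorted(net.hidden_edges):
        g.add_edge(a, b, displayed=False)
    return g


def write_graphml(net: ContextNetwork, context_set: ContextSet, path: str) -> None:
    nx.write_graphml(to_graphml_graph(net, context_set), path)
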