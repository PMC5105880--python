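"""Interaction-database ingestion, filtering and indexing.

Reads molecular-interaction records from PSI-MITAB 2.5/2.7 files or plain
two-column edge lists, normalizes identifiers, applies species /
interaction-type / ID-namespace filters, and indexes the surviving records
as a deduplicated, undirected, self-loop-free graph.  That graph is the
statistical universe for contextual-hub scoring: ``N`` (the background
population) is the number of genes with at least one qualifying
interaction in it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import networkx as nx

from .errors import EmptyDatabaseError, UnusableIdentifierError

log = logging.getLogger(__name__)

#: Registry-style minimum database size; smaller databases trigger a warning.
DEFAULT_MIN_EDGES = 10_000

_MI_TERM = re.compile(r"MI:\d{4}")
_PARENTHETICAL = re.compile(r"\([^)]*\)")


@dataclass(frozen=True)
class InteractionRecord:
    """One raw binary interaction as read from a file.

    Identifiers are kept verbatim (prefix and all) so namespace filtering
    can inspect them before normalization.
    """

    id_a: str
    id_b: str
    taxid_a: str = ""
    taxid_b: str = ""
    interaction_type: str = ""
    source_line: int = 1

    def __post_init__(self) -> None:
        if not self.id_a or not self.id_b:
            raise ValueError("interactor identifiers must be non-empty")
        if self.source_line < 1:
            raise ValueError("source_line must be >= 1")


@dataclass(frozen=True)
class FilterCriteria:
    """User-selected constraints a record must meet to enter the database.

    species
        NCBI taxon identifier (e.g. ``"9606"``); both interactors must
        match.  Records with an empty taxid field fail a set species
        filter.
    interaction_types
        Accepted interaction types.  An entry of the form ``MI:dddd`` is
        matched exactly against the MI identifier in the record; any
        other entry is a case-insensitive substring match on the type
        label (MITAB column 12 mixes both forms in the wild).
    id_namespace
        When set, only identifiers carrying this ``db:`` prefix
        (case-insensitive) are accepted; other records are dropped and
        counted in a log line.
    """

    species: str | None = None
    interaction_types: frozenset[str] | None = None
    id_namespace: str | None = None

    def __post_init__(self) -> None:
        if self.species is not None and not self.species.strip():
            raise ValueError("species filter, when set, must be non-empty")
        if self.interaction_types is not None:
            object.__setattr__(
                self, "interaction_types", frozenset(self.interaction_types)
            )
            if not self.interaction_types:
                raise ValueError("interaction_types filter, when set, must be non-empty")


@dataclass
class MitabParseReport:
    """Records plus bookkeeping from one parse pass."""

    records: list[InteractionRecord]
    n_malformed: int = 0


class InteractionDatabase:
    """Deduplicated undirected interaction graph over normalized IDs.

    Wraps a :class:`networkx.Graph`; every stored node has at least one
    edge, there are no self-loops, and adjacency is symmetric by
    construction.
    """

    def __init__(self, graph: nx.Graph):
        self._graph = graph

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return self._graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self._graph

    def nodes(self) -> list[str]:
        return sorted(self._graph.nodes)

    def neighbors(self, node: str) -> set[str]:
        return set(self._graph.adj[node])

    def degree(self, node: str) -> int:
        return self._graph.degree[node]

    def edges(self) -> list[tuple[str, str]]:
        """Distinct unordered pairs in stable lexicographic order."""
        return sorted(tuple(sorted(e)) for e in self._graph.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionDatabase):
            return NotImplemented
        return self.edges() == other.edges()


def normalize_id(raw: str) -> str:
    """Normalize a raw identifier to a canonical node ID.

    Strips surrounding whitespace, a leading ``db:`` prefix (text up to
    the first ``:``), parenthetical annotations, and case-folds to upper
    case.  Deliberately conservative: no cross-namespace mapping is
    attempted.

    >>> normalize_id("uniprotkb:p04637")
    'P04637'
    """
    if not raw:
        raise UnusableIdentifierError("unusable identifier: empty input")
    s = raw.strip()
    if ":" in s:
        s = s.split(":", 1)[1]
    s = _PARENTHETICAL.sub("", s).strip()
    if not s:
        raise UnusableIdentifierError(f"unusable identifier: {raw!r}")
    return s.upper()


def _strip_taxid(field_value: str) -> str:
    """``taxid:9606(human)`` -> ``9606``; ``-`` or empty -> ``""``."""
    s = field_value.strip()
    if not s or s == "-":
        return ""
    if ":" in s:
        s = s.split(":", 1)[1]
    return _PARENTHETICAL.sub("", s).strip()


def _id_prefix(raw: str) -> str:
    s = raw.strip()
    return s.split(":", 1)[0].lower() if ":" in s else ""


def parse_mitab(stream: IO[str] | Iterable[str]) -> MitabParseReport:
    """Parse a PSI-MITAB 2.5/2.7 stream into interaction records.

    Unique interactor identifiers come from columns 1-2, taxon IDs from
    columns 10-11 and the interaction type from column 12 (1-based).
    Lines with fewer than 15 tab-separated columns are skipped and
    counted, not fatal; ``#``-prefixed header/comment lines are ignored.

    Raises :class:`EmptyDatabaseError` if no line parses.
    """
    records: list[InteractionRecord] = []
    n_malformed = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            n_malformed += 1
            continue
        id_a, id_b = cols[0].strip(), cols[1].strip()
        if not id_a or id_a == "-" or not id_b or id_b == "-":
            n_malformed += 1
            continue
        records.append(
            InteractionRecord(
                id_a=id_a,
                id_b=id_b,
                taxid_a=_strip_taxid(cols[9]),
                taxid_b=_strip_taxid(cols[10]),
                interaction_type=cols[11].strip(),
                source_line=lineno,
            )
        )
    if not records:
        raise EmptyDatabaseError("empty database: no parseable interaction lines")
    if n_malformed:
        log.warning("skipped %d malformed MITAB line(s)", n_malformed)
    return MitabParseReport(records=records, n_malformed=n_malformed)


def parse_edgelist(stream: IO[str] | Iterable[str]) -> MitabParseReport:
    """Parse a two-column tab-separated edge list.

    No header required; ``#`` comment lines are skipped.  A
    zero-dependency fixture path alongside MITAB.
    """
    records: list[InteractionRecord] = []
    n_malformed = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = [c.strip() for c in line.split("\t")]
        if len(cols) < 2 or not cols[0] or not cols[1]:
            n_malformed += 1
            continue
        records.append(
            InteractionRecord(id_a=cols[0], id_b=cols[1], source_line=lineno)
        )
    if not records:
        raise EmptyDatabaseError("empty database: no parseable edge-list lines")
    if n_malformed:
        log.warning("skipped %d malformed edge-list line(s)", n_malformed)
    return MitabParseReport(records=records, n_malformed=n_malformed)


def _type_matches(record_type: str, accepted: frozenset[str]) -> bool:
    mi_in_record = _MI_TERM.search(record_type)
    for term in accepted:
        if _MI_TERM.fullmatch(term.strip()):
            if mi_in_record is not None and mi_in_record.group(0) == term.strip():
                return True
        elif term.strip().lower() in record_type.lower():
            return True
    return False


def build_database(
    records: Iterable[InteractionRecord],
    criteria: FilterCriteria | None = None,
) -> InteractionDatabase:
    """Filter, normalize and deduplicate records into a database.

    A record survives only if BOTH interactors match the species filter
    and its interaction type matches (when those filters are set).
    Self-interactions (identical normalized IDs) are disregarded, and
    multiple records for the same unordered pair collapse to one edge:
    the statistic downstream is over interactors, not evidence lines.

    Raises :class:`EmptyDatabaseError` when nothing survives filtering.
    """
    criteria = criteria or FilterCriteria()
    graph = nx.Graph()
    n_species_dropped = n_type_dropped = n_namespace_dropped = n_self = 0
    for rec in records:
        if criteria.id_namespace is not None:
            want = criteria.id_namespace.lower()
            if _id_prefix(rec.id_a) != want or _id_prefix(rec.id_b) != want:
                n_namespace_dropped += 1
                continue
        if criteria.species is not None:
            if rec.taxid_a != criteria.species or rec.taxid_b != criteria.species:
                n_species_dropped += 1
                continue
        if criteria.interaction_types is not None:
            if not _type_matches(rec.interaction_type, criteria.interaction_types):
                n_type_dropped += 1
                continue
        a, b = normalize_id(rec.id_a), normalize_id(rec.id_b)
        if a == b:
            n_self += 1
            continue
        graph.add_edge(a, b)
    dropped = n_species_dropped + n_type_dropped + n_namespace_dropped
    if dropped or n_self:
        log.info(
            "dropped records: %d species, %d type, %d namespace, %d self-interactions",
            n_species_dropped, n_type_dropped, n_namespace_dropped, n_self,
        )
    if graph.number_of_edges() == 0:
        raise EmptyDatabaseError("empty database after filtering")
    return InteractionDatabase(graph)


def background_size(db: InteractionDatabase) -> int:
    """``N``: genes with at least one interaction in the database."""
    return db.n_nodes


def check_min_size(db: InteractionDatabase, threshold: int = DEFAULT_MIN_EDGES) -> bool:
    """Warn when the database holds fewer interactions than ``threshold``.

    Registry databases below 10,000 interactions are conventionally
    excluded as backgrounds; here the rule is a warning, not an error,
    because it governs which databases are *offered*, not a mathematical
    requirement, and test fixtures are deliberately small.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    warn = db.n_edges < threshold
    if warn:
        log.warning(
            "database has %d interactions (< %d); background frequencies may be unreliable",
            db.n_edges, threshold,
        )
    return warn


def write_edgelist(db: InteractionDatabase, stream: IO[str]) -> None:
    """Write the database as a two-column TSV in stable lexicographic pair order."""
    for a, b in db.edges():
        stream.write(f"{a}\t{b}\n")


def load_database(
    path: str,
    db_format: str = "mitab",
    criteria: FilterCriteria | None = None,
) -> InteractionDatabase:
    """Read a database file (``mitab`` or ``edgelist``) and build the graph."""
    if db_format not in ("mitab", "edgelist"):
        raise ValueError(f"unknown database format: {db_format!r}")
    parser = parse_mitab if db_format == "mitab" else parse_edgelist
    with open(path, encoding="utf-8") as fh:
        report = parser(fh)
    return build_database(report.records, criteria)
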