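"""End-to-end pipeline: parse -> filter -> build -> score -> rank -> export.

One call runs the whole contextual-hub analysis from a database file and
a contextual gene table, and writes the score table, network exports
(SIF for display edges, GraphML for the full attributed network), the
contextual-vs-degree comparison and a run-metadata JSON.  Identical
configuration and inputs produce byte-identical score tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .database import (
    DEFAULT_MIN_EDGES,
    FilterCriteria,
    InteractionDatabase,
    background_size,
    check_min_size,
    load_database,
)
from .errors import CtxhubError
from .network import (
    ContextNetwork,
    ContextSet,
    Predicate,
    build_network,
    parse_context_table,
    resolve_context,
    write_graphml,
    write_sif,
)
from .stats import (
    HubRanking,
    HubScore,
    RankingComparison,
    compare_rankings,
    rank_hubs,
    score_network,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    db_path: str
    context_path: str
    out_dir: str
    db_format: str = "mitab"
    id_column: str = "gene"
    predicate: str = "all"
    species: str | None = None
    interaction_types: list[str] = field(default_factory=list)
    top: int = 20
    min_db_edges: int = DEFAULT_MIN_EDGES
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.top < 1:
            raise CtxhubError(f"top must be >= 1, got {self.top}")
        if self.db_format not in ("mitab", "edgelist"):
            raise CtxhubError(f"unknown database format: {self.db_format!r}")


@dataclass
class RunResult:
    """In-memory artifacts of a pipeline run."""

    db: InteractionDatabase
    context_set: ContextSet
    network: ContextNetwork
    scores: list[HubScore]
    contextual_ranking: HubRanking
    degree_ranking: HubRanking
    comparison: RankingComparison
    metadata: dict
    paths: dict[str, Path] = field(default_factory=dict)


def _prob(p: float | None) -> str:
    # repr round-trips doubles exactly
    return repr(float(p)) if p is not None else ""


def write_scores_tsv(
    scores: list[HubScore],
    network: ContextNetwork,
    context_set: ContextSet,
    contextual_ranking: HubRanking,
    degree_ranking: HubRanking,
    path: Path,
) -> None:
    """Score table in contextual-rank order with both rank columns."""
    rank_ctx = {s.node: i for i, s in enumerate(contextual_ranking.ordered, 1)}
    rank_deg = {s.node: i for i, s in enumerate(degree_ranking.ordered, 1)}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "node\trole\tcontextual\tn\tk\tp_raw\tp_adj\trank_contextual\trank_degree\n"
        )
        for s in contextual_ranking.ordered:
            fh.write(
                f"{s.node}\t{network.role(s.node)}\t"
                f"{str(s.node in context_set.contextual).lower()}\t"
                f"{s.n}\t{s.k}\t{_prob(s.p_raw)}\t{_prob(s.p_adj)}\t"
                f"{rank_ctx[s.node]}\t{rank_deg[s.node]}\n"
            )


def report_comparison(
    contextual: HubRanking, degree: HubRanking
) -> tuple[str, list[dict]]:
    """Side-by-side contextual-vs-degree report.

    Returns the human-readable text and the TSV-ready row dicts
    (rank, contextual node + adjusted p, degree node + degree).
    """
    cmp = compare_rankings(contextual, degree)
    ctx_top, deg_top = contextual.top_list, degree.top_list
    rows = []
    for i in range(max(len(ctx_top), len(deg_top))):
        c = ctx_top[i] if i < len(ctx_top) else None
        d = deg_top[i] if i < len(deg_top) else None
        rows.append(
            {
                "rank": i + 1,
                "contextual_node": c.node if c else "",
                "p_adj": _prob(c.p_adj) if c else "",
                "degree_node": d.node if d else "",
                "db_degree": d.db_degree if d else "",
            }
        )
    lines = [
        f"{'rank':>4}  {'contextual hub':<16}{'p_adj':<24}{'degree hub':<16}{'degree':>6}"
    ]
    for r in rows:
        lines.append(
            f"{r['rank']:>4}  {r['contextual_node']:<16}{r['p_adj']:<24}"
            f"{r['degree_node']:<16}{r['db_degree']!s:>6}"
        )
    lines.append(f"shared: {len(cmp.shared)}")
    lines.append(f"jaccard: {cmp.jaccard:.4f}")
    return "\n".join(lines) + "\n", rows


def _write_comparison_tsv(rows: list[dict], cmp: RankingComparison, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tcontextual_node\tp_adj\tdegree_node\tdb_degree\n")
        for r in rows:
            fh.write(
                f"{r['rank']}\t{r['contextual_node']}\t{r['p_adj']}\t"
                f"{r['degree_node']}\t{r['db_degree']}\n"
            )
        fh.write(f"# shared\t{len(cmp.shared)}\n")
        fh.write(f"# jaccard\t{cmp.jaccard!r}\n")


def analyze(
    db: InteractionDatabase, context, top: int = 20
) -> tuple[ContextSet, ContextNetwork, list[HubScore], HubRanking, HubRanking]:
    """Library-level core: resolve, expand, score, rank both ways."""
    context_set = resolve_context(context, db)
    network = build_network(db, context)
    scores = score_network(db, network, context_set)
    ctx_rank = rank_hubs(scores, "contextual", top=top)
    deg_rank = rank_hubs(scores, "degree", top=top)
    return context_set, network, scores, ctx_rank, deg_rank


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full analysis and write all run artifacts.

    On any component error the partially written outputs are removed and
    the error propagates (the CLI maps it to a nonzero exit).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "scores": out_dir / "scores.tsv",
        "sif": out_dir / "network.sif",
        "graphml": out_dir / "network.graphml",
        "comparison": out_dir / "comparison.tsv",
        "metadata": out_dir / "run.json",
    }
    try:
        criteria = FilterCriteria(
            species=config.species or None,
            interaction_types=(
                frozenset(config.interaction_types) if config.interaction_types else None
            ),
        )
        db = load_database(config.db_path, config.db_format, criteria)
        size_warning = check_min_size(db, config.min_db_edges)
        predicate = Predicate.parse(config.predicate)
        with open(config.context_path, encoding="utf-8") as fh:
            context = parse_context_table(fh, config.id_column, predicate)
        context_set, network, scores, ctx_rank, deg_rank = analyze(
            db, context, top=config.top
        )
        comparison = compare_rankings(ctx_rank, deg_rank)

        write_scores_tsv(scores, network, context_set, ctx_rank, deg_rank, paths["scores"])
        with open(paths["sif"], "w", encoding="utf-8", newline="\n") as fh:
            write_sif(network, fh)
        write_graphml(network, context_set, str(paths["graphml"]))
        text, rows = report_comparison(ctx_rank, deg_rank)
        _write_comparison_tsv(rows, comparison, paths["comparison"])

        metadata = {
            "version": __version__,
            "config": {
                "db_path": config.db_path,
                "db_format": config.db_format,
                "context_path": config.context_path,
                "id_column": config.id_column,
                "predicate": config.predicate,
                "species": config.species,
                "interaction_types": sorted(config.interaction_types),
                "top": config.top,
                "min_db_edges": config.min_db_edges,
                "out_dir": config.out_dir,
            },
            "N": background_size(db),
            "K": context_set.K,
            "db_edges": db.n_edges,
            "network_nodes": len(network.nodes),
            "n_seeds": len(network.seeds),
            "n_neighbors": len(network.neighbors),
            "m_tests": len(scores),
            "missing_contextual": context_set.missing,
            "shared_top": sorted(comparison.shared),
            "jaccard_top": comparison.jaccard,
            "warnings": (
                [f"database has {db.n_edges} interactions (< {config.min_db_edges})"]
                if size_warning
                else []
            ),
        }
        with open(paths["metadata"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        for p in paths.values():
            p.unlink(missing_ok=True)
        raise
    return RunResult(
        db=db,
        context_set=context_set,
        network=network,
        scores=scores,
        contextual_ranking=ctx_rank,
        degree_ranking=deg_rank,
        comparison=comparison,
        metadata=metadata,
        paths=paths,
    )
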