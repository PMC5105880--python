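import pytest

from ctxhub import (
    ContextInput,
    InteractionRecord,
    Predicate,
    build_database,
    resolve_context,
)

# Toy interactome used throughout: raw pairs include one duplicate (B-A)
# and one self-loop (F-F); the clean database has 7 edges over A..F with
# degrees A:3 B:2 C:3 D:2 E:3 F:1.
TOY_PAIRS = [
    ("A", "B"), ("B", "A"), ("A", "C"), ("A", "D"),
    ("B", "C"), ("C", "E"), ("D", "E"), ("E", "F"), ("F", "F"),
]
TOY_EDGES = sorted({("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"),
                    ("C", "E"), ("D", "E"), ("E", "F")})


def records_from_pairs(pairs):
    return [
        InteractionRecord(id_a=a, id_b=b, source_line=i)
        for i, (a, b) in enumerate(pairs, start=1)
    ]


def context_of(genes):
    """ContextInput listing `genes` with the identity predicate."""
    return ContextInput(
        rows=[(g, {}) for g in genes], predicate=Predicate.all_rows()
    )


@pytest.fixture
def toy_db():
    return build_database(records_from_pairs(TOY_PAIRS))


@pytest.fixture
def toy_context_bce(toy_db):
    """The {B, C, E} contextual set resolved against the toy database."""
    return resolve_context(context_of(["B", "C", "E"]), toy_db)
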