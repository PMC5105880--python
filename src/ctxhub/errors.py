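"""Exception hierarchy.

Every documented failure mode raises a subclass of :class:`CtxhubError`
so the command-line layer can map any component failure to a nonzero
exit with a single-line message.
"""


class CtxhubError(Exception):
    """Base class for all ctxhub errors."""


class EmptyDatabaseError(CtxhubError):
    """No parseable interaction records, or none survive filtering."""


class UnusableIdentifierError(CtxhubError):
    """An identifier normalizes to the empty string."""


class ContextError(CtxhubError):
    """Problems with the contextual gene table or predicate."""


class NetworkError(CtxhubError):
    """No seed genes found, or a node is outside the network."""


class StatError(CtxhubError):
    """Invalid statistical parameters (hypergeometric bounds, p-values)."""


class SpecError(CtxhubError):
    """Degenerate or infeasible synthetic-network specification."""
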