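"""Exception hierarchy shared across the package.

Every reader, simulator and analysis step raises one of these instead of a
bare ``ValueError`` so callers (and the CLI) can distinguish malformed files
from inconsistent inputs from statistical degeneracies.
"""


class DystogexError(Exception):
    """Base class for all package errors."""


class FormatError(DystogexError):
    """A file violates its declared on-disk format (bad header, duplicate
    gene symbol, non-integer count, too few fields on a GMT line...)."""


class ConsistencyError(DystogexError):
    """Two inputs that must agree do not (sample sets, matrix dimensions
    versus annotation lengths)."""


class ConfigError(DystogexError):
    """A simulation or pipeline configuration is invalid."""


class InputError(DystogexError):
    """Analysis input violates a precondition (missing stage, query gene
    set disjoint from the universe, single tissue...)."""


class ModelError(DystogexError):
    """A model cannot be fitted (rank-deficient design, constant
    indicator)."""


class DegenerateInputError(DystogexError):
    """Input is formally valid but statistically degenerate (e.g. a
    constant vector handed to a likelihood-based transform)."""


class EmptyResultError(DystogexError):
    """A filtering step removed everything."""


class DependencyError(DystogexError):
    """A pipeline stage requires an upstream output that was not produced."""
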