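"""Exception hierarchy.

Two top-level families matter to callers (and to the CLI, which maps them to
distinct exit codes): :class:`FormatError` for malformed input files and
:class:`ValidationError` for structurally or numerically invalid objects.
"""


class ComunetxError(Exception):
    """Base class for all package errors."""


class FormatError(ComunetxError):
    """An input file does not follow the expected dialect."""


class ValidationError(ComunetxError, ValueError):
    """An in-memory object violates a structural or numeric contract."""


class ShapeError(ValidationError):
    """Matrix dimensions do not match the declared cell-type set."""


class EmptyLayerError(ValidationError):
    """A layer carries no edge at all (all weights zero)."""


class ConsistencyError(ValidationError):
    """Two objects that must share a cell-type set (or pair-id set) do not."""
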