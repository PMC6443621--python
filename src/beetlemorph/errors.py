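"""Exception hierarchy.

All package-specific failures derive from :class:`BeetlemorphError` so
callers (and the CLI) can distinguish user/data errors from internal bugs.
"""


class BeetlemorphError(Exception):
    """Base class for all errors raised by beetlemorph."""


class TpsParseError(BeetlemorphError):
    """A TPS file line could not be parsed; the message names the line."""


class TpsIntegrityError(BeetlemorphError):
    """Declared LM=/POINTS= counts disagree with the coordinates present."""


class EmptyInputError(BeetlemorphError):
    """An operation received a record or set with nothing to work on."""


class DegenerateShapeError(BeetlemorphError):
    """A configuration or curve has no geometric extent (coincident points)."""


class ShapeMismatchError(BeetlemorphError):
    """Configurations with incompatible landmark counts were combined."""


class ReconciliationError(BeetlemorphError):
    """Tree tip labels and taxa-table groups could not be reconciled."""


class ParameterError(BeetlemorphError):
    """A parameter value is outside its valid domain."""
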