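"""Exception hierarchy for the beltscan pipeline.

Every stage raises a subclass of :class:`BeltscanError`, so callers can
catch pipeline failures without swallowing programming errors.
"""


class BeltscanError(Exception):
    """Base class for all beltscan errors."""


class ValidationError(BeltscanError, ValueError):
    """An input value violates a documented precondition."""


class DimensionError(BeltscanError, ValueError):
    """Array/port/feature dimensions do not match the contract."""


class ParseError(BeltscanError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(BeltscanError, ValueError):
    """A tabular file is missing required columns."""


class AlignmentError(BeltscanError, ValueError):
    """Two sweeps are on different frequency grids (no silent resampling)."""


class LeakageError(BeltscanError, RuntimeError):
    """A case id appears on both sides of a train/test partition."""
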