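"""Exception hierarchy.

Exit-code mapping used by the CLI: config errors (2), data/parse errors (3),
numeric/degenerate errors (4).
"""


class DualskelError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(DualskelError):
    """Invalid configuration or incompatible stream parameters."""

    exit_code = 2


class ParseError(DualskelError):
    """Malformed landmark file; message names the offending line."""

    exit_code = 3


class StructuralError(DualskelError):
    """Sequence-level structural violation (e.g. non-contiguous frames)."""

    exit_code = 3


class AbsentJointError(DualskelError):
    """A position with present=False was dereferenced."""

    exit_code = 4


class DegenerateGeometryError(DualskelError):
    """Too few common joints for a trustworthy spatial registration."""

    exit_code = 4


class InsufficientOverlapError(DualskelError):
    """Shifted streams overlap on too few frames."""

    exit_code = 4


class DegenerateFitError(DualskelError):
    """Regression input has no usable spread (constant regressor)."""

    exit_code = 4


class CalibrationError(DualskelError):
    """Measurement-noise calibration could not be performed."""

    exit_code = 4


class EmptyResultError(DualskelError):
    """An operation produced or received an empty collection."""

    exit_code = 4
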