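"""Exception hierarchy shared across the package.

Every error a caller is expected to catch derives from :class:`VoxelProtError`;
precondition violations additionally derive from :class:`ValueError` so that
generic validation code keeps working.
"""


class VoxelProtError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(VoxelProtError, ValueError):
    """A precondition on an operation's arguments was violated."""


class UndefinedRatioError(VoxelProtError, ZeroDivisionError):
    """A ratio was requested whose denominator context is empty."""

    def __init__(self, context: str):
        self.context = context
        super().__init__(f"ratio undefined: no counts in denominator context {context!r}")


class UndefinedCorrelationError(VoxelProtError, ValueError):
    """Correlation requested for a zero-variance row or column."""

    def __init__(self, label, axis: str):
        self.label = label
        self.axis = axis
        super().__init__(f"correlation undefined: zero variance in {axis} {label!r}")


class IncompleteMatrixError(VoxelProtError, ValueError):
    """An operation requiring a complete matrix received missing values."""


class EmptySelectionError(VoxelProtError, ValueError):
    """A filter or selection produced an empty result where that is not allowed."""


class InsufficientOverlapError(VoxelProtError, ValueError):
    """Two tables share too few accessions for the requested comparison."""


class NotFoundError(VoxelProtError, KeyError):
    """A requested accession or identifier is absent."""


class ConfigError(VoxelProtError, ValueError):
    """A run configuration failed schema validation."""


class DataError(VoxelProtError, ValueError):
    """An input file parsed but its content violates the expected contract."""
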