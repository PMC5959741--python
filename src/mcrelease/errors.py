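"""Exception hierarchy for mcrelease."""


class MCReleaseError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MCReleaseError, ValueError):
    """Invalid cylinder geometry (e.g. radius not greater than the shell width)."""


class EmptyCloudError(MCReleaseError, ValueError):
    """An operation requiring a non-empty particle cloud received an empty one."""


class PackingError(MCReleaseError, RuntimeError):
    """Minimum-distance sampling could not reach the requested point count."""

    def __init__(self, requested: int, achieved: int, attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.attempts = attempts
        super().__init__(
            f"could not pack {requested} points (best: {achieved} "
            f"after {attempts} attempts)"
        )


class ShellExhaustedError(MCReleaseError, RuntimeError):
    """The cylinder radius has shrunk to the shell width; no leak shell remains."""


class ConfigError(MCReleaseError, ValueError):
    """Inconsistent or unknown simulation / GA configuration."""


class CurveError(MCReleaseError, ValueError):
    """A release curve violates its structural invariants."""


class FormatError(MCReleaseError, ValueError):
    """A tabular input file is malformed; carries the offending row index."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class FitInputError(MCReleaseError, ValueError):
    """A regression received input it cannot fit (too few points, bad domain)."""


class ExtrapolationError(MCReleaseError, ValueError):
    """Observed times fall outside the simulated range after alignment."""


class InferenceError(MCReleaseError, RuntimeError):
    """The genetic algorithm could not evaluate any candidate."""
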