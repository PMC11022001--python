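"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ValidationError -> 2,
ConvergenceError -> 3, I/O errors -> 4.
"""


class AneumechError(Exception):
    """Base class for all package errors."""


class ValidationError(AneumechError, ValueError):
    """Invalid specification, parameter or input data."""


class ConvergenceError(AneumechError, RuntimeError):
    """A numerical solve failed (e.g. pressure beyond the membrane limit point)."""


class GeometryError(AneumechError, RuntimeError):
    """Degenerate or self-intersecting geometry."""


class RegistrationError(AneumechError, RuntimeError):
    """Rigid overlay of two masks failed to reach a usable overlap."""


class ExtrapolationError(AneumechError, ValueError):
    """Response-surface evaluation requested outside the fitted parameter box."""
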