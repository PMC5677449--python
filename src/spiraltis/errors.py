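"""Exception types shared across the package."""


class SpiralTisError(Exception):
    """Base class for package errors."""


class FormatError(SpiralTisError, ValueError):
    """A trace table is structurally malformed (e.g. a required column is missing)."""


class TrialValidationError(SpiralTisError, ValueError):
    """A spiral trial violates a data-model invariant."""


class DegenerateInputError(SpiralTisError, ValueError):
    """An input is too small or too degenerate for the requested computation."""
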