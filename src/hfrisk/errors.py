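"""Exception hierarchy for hfrisk.

All user-facing failures derive from :class:`HfriskError` so callers (and the
CLI) can distinguish bad input from genuine bugs.
"""


class HfriskError(Exception):
    """Base class for all hfrisk errors."""


class ValidationError(HfriskError):
    """Raised when an input table violates a structural invariant."""


class ConvergenceError(HfriskError):
    """Raised when the total-relation series does not converge
    (spectral radius of the normalized matrix is >= 1)."""


class FixtureError(HfriskError):
    """Raised for unknown fixture names."""


class PipelineError(HfriskError):
    """Raised when a pipeline stage fails; message carries the stage label."""
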