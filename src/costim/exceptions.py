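"""Exception hierarchy for the costim pipeline.

All errors derive from :class:`CostimError` so callers can catch pipeline
failures with a single except clause while still distinguishing configuration
problems from degenerate-data problems.
"""


class CostimError(Exception):
    """Base class for all costim errors."""


class ConfigurationError(CostimError, ValueError):
    """A config object or file violates its invariants."""


class InsufficientBaselineError(CostimError, ValueError):
    """A force trace does not contain the required pre-stimulus baseline."""


class WindowError(CostimError, ValueError):
    """An analysis window falls outside the recorded trace or is ill-formed."""


class UndefinedDirectionError(CostimError, ValueError):
    """A direction-based statistic was requested for a (near-)zero vector.

    Raised instead of silently returning 0 degrees, which would corrupt
    circular summaries downstream.
    """


class DegenerateDataError(CostimError, ValueError):
    """Input data are too small or degenerate for the requested statistic."""
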