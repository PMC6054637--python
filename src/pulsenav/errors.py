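"""Exception hierarchy for pulsenav.

All user-facing errors derive from :class:`PulsenavError` so callers (and the
CLI) can distinguish data/parameter problems from genuine bugs.
"""


class PulsenavError(Exception):
    """Base class for all pulsenav errors."""


class ParameterError(PulsenavError, ValueError):
    """A parameter value is invalid for the requested operation."""


class DataError(PulsenavError, ValueError):
    """Input data violates the format or content contract."""


class DegenerateTraceError(DataError):
    """A trace is constant (or otherwise degenerate) where variation is required."""


class InfeasibleGradientError(ParameterError):
    """A target stimulus profile cannot be realised by the mixing chamber.

    Carries the first violating time so the user can reshape the target.
    """

    def __init__(self, time_s: float, fraction: float):
        self.time_s = float(time_s)
        self.fraction = float(fraction)
        super().__init__(
            f"mixing fraction {fraction:.4g} outside [0, 1] first at "
            f"t = {time_s:.4g} s; the chamber cannot produce this gradient"
        )


class UndefinedTestError(PulsenavError, ValueError):
    """A statistical test is undefined for the given data (e.g. all-zero differences)."""


class FitError(PulsenavError, RuntimeError):
    """A model fit failed or is undefined for the given window."""
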