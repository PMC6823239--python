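"""Exception hierarchy for the racir package.

Every error a pipeline stage can raise derives from :class:`RacirError`,
so batch drivers can isolate per-file failures with a single except clause.
"""


class RacirError(Exception):
    """Base class for all errors raised by this package."""


class CurveError(RacirError, ValueError):
    """A curve violates a structural invariant (missing columns, bad time axis)."""


class EmptyCurveError(CurveError):
    """A curve has no usable records."""


class InvalidAreaError(RacirError, ValueError):
    """Leaf area is zero or negative where a positive area is required."""


class InvalidHumidityError(RacirError, ValueError):
    """A water mole fraction is outside the physical range (>= 1000 mmol mol-1)."""


class InvalidWindowError(RacirError, ValueError):
    """A Ci exclusion window has lo > hi."""


class NoSteadyStateError(RacirError):
    """No run of in-threshold deltas long enough to declare steady state."""

    def __init__(self, threshold: float, min_run_length: int, longest_run: int):
        self.threshold = threshold
        self.min_run_length = min_run_length
        self.longest_run = longest_run
        super().__init__(
            f"no steady-state run found: need {min_run_length} consecutive "
            f"|delta| <= {threshold} but the longest run observed was "
            f"{longest_run} points"
        )


class TooFewPointsError(RacirError, ValueError):
    """Not enough points for the requested fit."""


class DomainMismatchError(RacirError):
    """Too few records fall inside an empty-chamber model's reference-CO2 domain."""


class NonConvergenceError(RacirError):
    """Nonlinear fit failed to converge from every starting point."""
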