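"""Exception hierarchy for the fitting pipeline.

Every stage raises a subclass of :class:`LVFitError`, so callers (and the CLI)
can attach stage context and map failures to exit codes.
"""


class LVFitError(Exception):
    """Base class for all package errors."""


class ValidationError(LVFitError, ValueError):
    """Malformed input data or inconsistent parameter structures."""


class EstimationError(LVFitError):
    """Linear estimation failed (rank deficiency, too few usable records)."""


class SimulationError(LVFitError):
    """ODE integration failed or diverged.

    ``last_time`` carries the last time point the integrator reached, when
    known.
    """

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


class ScenarioError(LVFitError):
    """Synthetic-data scenario could not be generated."""
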