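"""Exception hierarchy for simulation and measurement failures."""


class SappaError(Exception):
    """Base class for all package-specific errors."""


class SingularDenominatorError(SappaError):
    """The higher-order nonlinearity denominator 1 - eps*|z|^2 is not positive."""


class DegenerateInputError(SappaError):
    """Normalized stimulus requested at a point where the combined input is zero."""


class HistoryUnderflowError(SappaError):
    """A delayed lookup was requested before the start of the stored history."""


class IntegrationBlowUpError(SappaError):
    """The oscillator state became non-finite (or unreasonably large)."""

    def __init__(self, t: float):
        self.t = t
        super().__init__(f"oscillator state diverged at t = {t:.4f} s")


class MeasurementError(SappaError):
    """A trajectory did not yield the events required by a measurement."""


class InsufficientTurnsError(SappaError):
    """Fewer than three alternation turns are available for the lead/lag statistic."""


class TurnLockupError(SappaError):
    """Turn-taking oscillators stopped alternating (no phase advance)."""


class ConfigError(SappaError):
    """Invalid or degenerate configuration (empty grid, bad value, unknown key)."""


class NoFitError(SappaError):
    """Every candidate in a parameter grid search failed to synchronize."""
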