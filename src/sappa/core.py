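"""Canonical Hopf oscillator with delayed recurrent feedback, and its inputs.

The oscillator state is a single complex number ``z``.  Its evolution is

    dz/dt = f_hat * [ z * (alpha + i*2*pi + beta1*|z|^2
                           + eps*beta2*|z|^4 / (1 - eps*|z|^2)) + F ]
            - D * z(t - tau)

where ``f_hat = f + delta`` is the (possibly detuned) natural frequency in
Hz, ``F`` is an external/feedback input, and the last term is the
oscillator's own activity fed back with amplitude ``D`` after a delay of
``tau`` seconds.  With ``alpha = 1``, ``beta1 = -1``, ``beta2 = eps = 0``
the unforced, delay-free system settles on the unit circle and rotates at
``f`` Hz; the delayed feedback term is what produces anticipatory
phase-leads when the oscillator entrains to a periodic stimulus.

The input ``F`` takes a handful of forms used by the simulated tasks:

* a unit sinusoid ``exp(i*2*pi*fs*t)`` (a metronome), possibly negated
  (anti-phase role) or replaced by a square wave,
* the sinusoid combined with the oscillator's instantaneous activity,
  ``(exp(i*2*pi*fs*t) + A*z) / |exp(i*2*pi*fs*t) + A*z|`` — "hearing
  yourself" while listening to the metronome,
* pure oscillator activity ``A*z_self`` or a partner's transmitted
  activity ``z_partner`` (turn-taking without a metronome).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, replace
from enum import Enum

from .errors import ConfigError, DegenerateInputError, SingularDenominatorError

TWO_PI = 2.0 * math.pi

#: Parameter values shared by both performer profiles.
PROFILE_TAU_S = 0.222
PROFILE_A = -0.5
#: Delayed-feedback amplitudes distinguishing the two profiles.
MUSICIAN_D = 0.05
NONMUSICIAN_D = 0.36


@dataclass(frozen=True)
class OscillatorParams:
    """Parameters of the delayed-feedback Hopf oscillator.

    alpha, beta1, beta2, epsilon : dimensionless dynamics parameters.
    f : natural frequency in Hz (> 0).
    D : amplitude of the delayed recurrent feedback (>= 0).
    tau : recurrent-feedback delay in seconds (>= 0).
    A : coefficient applied to the oscillator's own (or a partner's)
        instantaneous activity when it appears in the input F.
    delta : additive frequency detuning in Hz (default 0).
    """

    alpha: float = 1.0
    beta1: float = -1.0
    beta2: float = 0.0
    epsilon: float = 0.0
    f: float = 1.0
    D: float = 0.0
    tau: float = 0.0
    A: float = PROFILE_A
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not self.f > 0:
            raise ConfigError(f"natural frequency f must be positive, got {self.f}")
        if self.tau < 0:
            raise ConfigError(f"feedback delay tau must be >= 0, got {self.tau}")
        if self.D < 0:
            raise ConfigError(f"feedback amplitude D must be >= 0, got {self.D}")

    @property
    def effective_f(self) -> float:
        """Detuned frequency f + delta in Hz."""
        return self.f + self.delta


def musician_params(f: float = 1.0, **overrides) -> OscillatorParams:
    """Oscillator parameterization fitted to musician tapping (D = 0.05)."""
    kw = dict(f=f, D=MUSICIAN_D, tau=PROFILE_TAU_S, A=PROFILE_A)
    kw.update(overrides)
    return OscillatorParams(**kw)


def nonmusician_params(f: float = 1.0, **overrides) -> OscillatorParams:
    """Oscillator parameterization fitted to non-musician tapping (D = 0.36)."""
    kw = dict(f=f, D=NONMUSICIAN_D, tau=PROFILE_TAU_S, A=PROFILE_A)
    kw.update(overrides)
    return OscillatorParams(**kw)


def profile_params(profile: str, f: float = 1.0, **overrides) -> OscillatorParams:
    """Look up a performer profile by name ('musician' or 'nonmusician')."""
    if profile == "musician":
        return musician_params(f=f, **overrides)
    if profile in ("nonmusician", "non-musician"):
        return nonmusician_params(f=f, **overrides)
    raise ConfigError(f"unknown profile {profile!r}; expected 'musician' or 'nonmusician'")


class StimulusKind(str, Enum):
    """Shape of the external periodic carrier."""

    NONE = "none"
    SINUSOID = "sinusoid"
    ANTIPHASE_SINUSOID = "antiphase_sinusoid"
    SQUARE_WAVE = "square_wave"
    SELF_ONLY = "self_only"


class FeedbackMode(str, Enum):
    """How oscillator activity enters the input F alongside the carrier."""

    OFF = "off"
    CONSTANT_SELF = "constant_self"
    HALF_CYCLE_SELF = "half_cycle_self"
    DUET_ALTERNATING = "duet_alternating"
    TURN_TAKING = "turn_taking"


@dataclass(frozen=True)
class StimulusSpec:
    """Input configuration for a single oscillator.

    kind : carrier shape (none for turn-taking / pure self-input runs).
    fs : carrier frequency in Hz; equal to the oscillator's f unless a
        detuning variant explicitly differs.
    feedback_mode : which oscillator-activity term is mixed into F.
    normalize : apply the unit-magnitude normalization whenever the
        carrier is combined with oscillator activity.
    tl : transmission latency in seconds applied to a partner's signal
        (turn-taking only).
    literal_partner_sign : in duet alternation, negate the coefficient on
        the partner's activity (-A instead of A).  The default keeps a
        single convention — the coefficient A, carrying its own sign, on
        every non-delayed activity term.
    """

    kind: StimulusKind = StimulusKind.SINUSOID
    fs: float = 1.0
    feedback_mode: FeedbackMode = FeedbackMode.OFF
    normalize: bool = True
    tl: float = 0.0
    literal_partner_sign: bool = False

    def __post_init__(self) -> None:
        if self.kind not in (StimulusKind.NONE, StimulusKind.SELF_ONLY) and not self.fs > 0:
            raise ConfigError(f"carrier frequency fs must be positive, got {self.fs}")
        if self.tl < 0:
            raise ConfigError(f"transmission latency must be >= 0, got {self.tl}")
        if self.tl > 0 and self.feedback_mode is not FeedbackMode.TURN_TAKING:
            raise ConfigError("a transmission latency only applies to turn_taking coupling")

    def with_feedback(self, mode: FeedbackMode) -> "StimulusSpec":
        return replace(self, feedback_mode=mode)


def carrier(t: float, spec: StimulusSpec) -> complex:
    """External periodic carrier at time t (0 for carrier-free kinds)."""
    k = spec.kind
    if k is StimulusKind.SINUSOID:
        return cmath.exp(1j * TWO_PI * spec.fs * t)
    if k is StimulusKind.ANTIPHASE_SINUSOID:
        return -cmath.exp(1j * TWO_PI * spec.fs * t)
    if k is StimulusKind.SQUARE_WAVE:
        c = math.cos(TWO_PI * spec.fs * t)
        return complex(1.0 if c >= 0.0 else -1.0, 0.0)
    if k in (StimulusKind.NONE, StimulusKind.SELF_ONLY):
        return 0j
    raise ConfigError(f"unknown stimulus kind {k!r}")


def _combine(c: complex, fb: complex, normalize: bool) -> complex:
    total = c + fb
    if not normalize:
        return total
    mag = abs(total)
    if mag < 1e-12:
        raise DegenerateInputError(
            "combined carrier + activity input has zero magnitude; cannot normalize"
        )
    return total / mag


def stimulus_input(
    t: float,
    spec: StimulusSpec,
    z_self: complex,
    A: float,
    z_partner: complex | None = None,
    active: bool | None = None,
) -> complex:
    """Input F(t) delivered to one oscillator.

    ``z_partner`` must be supplied (already latency-shifted by the caller)
    for duet and turn-taking modes; ``active`` states whether this
    oscillator currently holds the turn in turn-taking mode.
    """
    mode = spec.feedback_mode
    if mode is FeedbackMode.OFF:
        if spec.kind is StimulusKind.SELF_ONLY:
            return A * z_self
        return carrier(t, spec)
    if mode is FeedbackMode.CONSTANT_SELF:
        return _combine(carrier(t, spec), A * z_self, spec.normalize)
    if mode is FeedbackMode.HALF_CYCLE_SELF:
        # Half-cycle boundary defined on the carrier's phase: first half
        # of each stimulus period is carrier-only, second half adds A*z.
        frac = (spec.fs * t) % 1.0
        if frac < 0.5:
            return carrier(t, spec)
        return _combine(carrier(t, spec), A * z_self, spec.normalize)
    if mode is FeedbackMode.DUET_ALTERNATING:
        if z_partner is None:
            raise ConfigError("duet_alternating input requires a partner state")
        # The shared activity source toggles between the two oscillators
        # twice per stimulus period, starting with each model's own state.
        slot = int(math.floor(2.0 * spec.fs * t)) % 2
        if slot == 0:
            fb = A * z_self
        else:
            coeff = -A if spec.literal_partner_sign else A
            fb = coeff * z_partner
        return _combine(carrier(t, spec), fb, spec.normalize)
    if mode is FeedbackMode.TURN_TAKING:
        if active is None:
            raise ConfigError("turn_taking input requires the active/passive role")
        if active:
            return A * z_self
        if z_partner is None:
            raise ConfigError("turn_taking input requires a partner state when passive")
        return z_partner
    raise ConfigError(f"unknown feedback mode {mode!r}")


def sappa_derivative(
    z: complex,
    z_delayed: complex,
    F: complex,
    params: OscillatorParams,
) -> complex:
    """Right-hand side dz/dt of the delayed-feedback oscillator.

    ``z_delayed`` is z(t - tau), supplied by the integrator's history
    buffer.  Pure function; raises if the higher-order nonlinearity
    denominator 1 - eps*|z|^2 is not positive.
    """
    mag2 = z.real * z.real + z.imag * z.imag
    lin = params.alpha + params.beta1 * mag2
    if params.epsilon != 0.0:
        denom = 1.0 - params.epsilon * mag2
        if denom <= 0.0:
            raise SingularDenominatorError(
                f"eps*|z|^2 = {params.epsilon * mag2:.4f} >= 1; nonlinearity denominator vanished"
            )
        lin += params.epsilon * params.beta2 * mag2 * mag2 / denom
    return params.effective_f * (z * complex(lin, TWO_PI) + F) - params.D * z_delayed
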