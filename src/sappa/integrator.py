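"""Fixed-step integration of the delayed-feedback oscillator.

The model is a delay differential equation, so every step needs the state
``tau`` seconds in the past (and, for coupled oscillators, the partner's
state one transmission latency in the past).  Integration uses a classical
4th-order Runge-Kutta step on a uniform grid; delays are snapped to the
nearest grid multiple so that on-grid history lookups are exact, and the
half-step stage lookups fall mid-grid where the buffer interpolates
linearly.  Pre-history (t < 0) is held constant at the initial state, the
standard convention for delay equations.

All integration here is deterministic: identical inputs produce identical
trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core
from .core import FeedbackMode, OscillatorParams, StimulusKind, StimulusSpec, sappa_derivative, stimulus_input
from .errors import ConfigError, HistoryUnderflowError, IntegrationBlowUpError, TurnLockupError

#: Default integration step (seconds).
DEFAULT_DT = 1e-3
#: State magnitude beyond which a run is declared divergent.
BLOWUP_MAGNITUDE = 1e6


class DelayBuffer:
    """Uniform-grid history of complex samples with linear interpolation.

    Samples are stored in time order starting at ``t0`` with spacing
    ``dt``.  Lookups at on-grid times return the stored sample exactly;
    lookups between grid points interpolate linearly between the two
    bracketing samples.  Querying before ``t0`` raises.
    """

    __slots__ = ("dt", "t0", "samples")

    def __init__(self, dt: float, t0: float, samples=None):
        if dt <= 0:
            raise ConfigError(f"buffer step dt must be positive, got {dt}")
        self.dt = float(dt)
        self.t0 = float(t0)
        self.samples: list[complex] = list(samples) if samples is not None else []

    def append(self, z: complex) -> None:
        self.samples.append(z)

    @property
    def t_last(self) -> float:
        return self.t0 + (len(self.samples) - 1) * self.dt

    def lookup(self, t_query: float) -> complex:
        """z at ``t_query`` by linear interpolation on the stored grid."""
        x = (t_query - self.t0) / self.dt
        if x < -1e-9:
            raise HistoryUnderflowError(
                f"lookup at t = {t_query:.6f} s precedes history start t0 = {self.t0:.6f} s"
            )
        n = len(self.samples)
        i = int(math.floor(x))
        if i < 0:
            i = 0
        frac = x - i
        if i >= n - 1:
            if x > n - 1 + 1e-9:
                raise HistoryUnderflowError(
                    f"lookup at t = {t_query:.6f} s is beyond the last stored sample"
                )
            return self.samples[n - 1]
        if frac == 0.0:
            return self.samples[i]
        s0 = self.samples[i]
        s1 = self.samples[i + 1]
        return s0 + (s1 - s0) * frac


def delayed_lookup(buffer: DelayBuffer, t_query: float) -> complex:
    """Functional alias for :meth:`DelayBuffer.lookup`."""
    return buffer.lookup(t_query)


@dataclass
class Trajectory:
    """Uniformly sampled oscillator state with its input trace."""

    times: np.ndarray
    z: np.ndarray
    F: np.ndarray
    params: OscillatorParams
    spec: StimulusSpec
    dt: float

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.z) == len(self.F)):
            raise ConfigError("trajectory arrays must share one length")

    @property
    def re_z(self) -> np.ndarray:
        return self.z.real

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "re_z": self.z.real,
                "im_z": self.z.imag,
                "re_F": self.F.real,
                "im_F": self.F.imag,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _snap_steps(delay_s: float, dt: float) -> int:
    """Delay expressed as a whole number of grid steps (nearest multiple)."""
    return int(round(delay_s / dt))


def _check_finite(z: complex, t: float) -> None:
    m = abs(z)
    if not math.isfinite(m) or m > BLOWUP_MAGNITUDE:
        raise IntegrationBlowUpError(t)


def _init_state(init_phase: float, init_magnitude: float) -> complex:
    return init_magnitude * complex(math.cos(init_phase), math.sin(init_phase))


def integrate(
    params: OscillatorParams,
    spec: StimulusSpec,
    duration: float,
    dt: float = DEFAULT_DT,
    init_phase: float = 0.0,
    init_magnitude: float = 1.0,
) -> Trajectory:
    """Integrate a single driven oscillator for ``duration`` seconds.

    Valid for the single-oscillator feedback modes (off, constant_self,
    half_cycle_self, and carrier-free self-input); coupled modes need
    :func:`integrate_pair` or :func:`integrate_turn_taking`.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    if spec.feedback_mode in (FeedbackMode.DUET_ALTERNATING, FeedbackMode.TURN_TAKING):
        raise ConfigError(f"{spec.feedback_mode.value} coupling requires a paired integrator")

    n_steps = int(round(duration / dt))
    tau_steps = _snap_steps(params.tau, dt)
    z0 = _init_state(init_phase, init_magnitude)
    A = params.A

    # zs[0 .. tau_steps-1] is constant pre-history; zs[tau_steps + i] = z(i*dt).
    zs: list[complex] = [z0] * (tau_steps + 1)
    cur = tau_steps
    half = 0.5 * dt
    sixth = dt / 6.0

    def zdel(stage_offset: float) -> complex:
        if tau_steps == 0:
            return None  # caller substitutes the stage state
        x = cur + stage_offset - tau_steps
        i = int(x)
        frac = x - i
        if frac == 0.0:
            return zs[i]
        return zs[i] + (zs[i + 1] - zs[i]) * frac

    for i in range(n_steps):
        t = i * dt
        z = zs[cur]

        d0 = zdel(0.0)
        dh = zdel(0.5)
        d1 = zdel(1.0)

        k1 = sappa_derivative(z, d0 if tau_steps else z, stimulus_input(t, spec, z, A), params)
        zk = z + half * k1
        k2 = sappa_derivative(zk, dh if tau_steps else zk, stimulus_input(t + half, spec, zk, A), params)
        zk = z + half * k2
        k3 = sappa_derivative(zk, dh if tau_steps else zk, stimulus_input(t + half, spec, zk, A), params)
        zk = z + dt * k3
        k4 = sappa_derivative(zk, d1 if tau_steps else zk, stimulus_input(t + dt, spec, zk, A), params)

        z_new = z + sixth * (k1 + 2.0 * (k2 + k3) + k4)
        _check_finite(z_new, t + dt)
        zs.append(z_new)
        cur += 1

    times = np.arange(n_steps + 1) * dt
    z_arr = np.asarray(zs[tau_steps:], dtype=complex)
    F_arr = np.asarray(
        [stimulus_input(i * dt, spec, z_arr[i], A) for i in range(n_steps + 1)], dtype=complex
    )
    return Trajectory(times=times, z=z_arr, F=F_arr, params=params, spec=spec, dt=dt)


def integrate_pair(
    params1: OscillatorParams,
    params2: OscillatorParams,
    spec1: StimulusSpec,
    spec2: StimulusSpec,
    duration: float,
    dt: float = DEFAULT_DT,
    init_phase: tuple[float, float] = (0.0, 0.0),
    init_magnitude: tuple[float, float] = (1.0, 1.0),
) -> tuple[Trajectory, Trajectory]:
    """Integrate two oscillators on a shared grid with mutual instantaneous coupling.

    Both oscillators are advanced jointly (one Runge-Kutta step on the
    stacked state), so non-delayed partner terms are evaluated at the
    stage states — the coupled system is treated as one ODE system, with
    only the recurrent-feedback terms read from history.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    n_steps = int(round(duration / dt))
    tau1 = _snap_steps(params1.tau, dt)
    tau2 = _snap_steps(params2.tau, dt)
    z10 = _init_state(init_phase[0], init_magnitude[0])
    z20 = _init_state(init_phase[1], init_magnitude[1])

    zs1: list[complex] = [z10] * (tau1 + 1)
    zs2: list[complex] = [z20] * (tau2 + 1)
    cur1, cur2 = tau1, tau2
    half = 0.5 * dt
    sixth = dt / 6.0
    A1, A2 = params1.A, params2.A

    def zdel(zs, cur, tau_steps, stage_offset):
        if tau_steps == 0:
            return None
        x = cur + stage_offset - tau_steps
        i = int(x)
        frac = x - i
        if frac == 0.0:
            return zs[i]
        return zs[i] + (zs[i + 1] - zs[i]) * frac

    def rhs(t, z1, z2, off):
        d1 = zdel(zs1, cur1, tau1, off)
        d2 = zdel(zs2, cur2, tau2, off)
        F1 = stimulus_input(t, spec1, z1, A1, z_partner=z2)
        F2 = stimulus_input(t, spec2, z2, A2, z_partner=z1)
        dz1 = sappa_derivative(z1, d1 if tau1 else z1, F1, params1)
        dz2 = sappa_derivative(z2, d2 if tau2 else z2, F2, params2)
        return dz1, dz2

    for i in range(n_steps):
        t = i * dt
        z1, z2 = zs1[cur1], zs2[cur2]
        a1, a2 = rhs(t, z1, z2, 0.0)
        b1, b2 = rhs(t + half, z1 + half * a1, z2 + half * a2, 0.5)
        c1, c2 = rhs(t + half, z1 + half * b1, z2 + half * b2, 0.5)
        e1, e2 = rhs(t + dt, z1 + dt * c1, z2 + dt * c2, 1.0)
        z1n = z1 + sixth * (a1 + 2.0 * (b1 + c1) + e1)
        z2n = z2 + sixth * (a2 + 2.0 * (b2 + c2) + e2)
        _check_finite(z1n, t + dt)
        _check_finite(z2n, t + dt)
        zs1.append(z1n)
        zs2.append(z2n)
        cur1 += 1
        cur2 += 1

    times = np.arange(n_steps + 1) * dt
    z1_arr = np.asarray(zs1[tau1:], dtype=complex)
    z2_arr = np.asarray(zs2[tau2:], dtype=complex)
    F1_arr = np.asarray(
        [stimulus_input(i * dt, spec1, z1_arr[i], A1, z_partner=z2_arr[i]) for i in range(n_steps + 1)],
        dtype=complex,
    )
    F2_arr = np.asarray(
        [stimulus_input(i * dt, spec2, z2_arr[i], A2, z_partner=z1_arr[i]) for i in range(n_steps + 1)],
        dtype=complex,
    )
    return (
        Trajectory(times=times, z=z1_arr, F=F1_arr, params=params1, spec=spec1, dt=dt),
        Trajectory(times=times, z=z2_arr, F=F2_arr, params=params2, spec=spec2, dt=dt),
    )


@dataclass
class Turn:
    """One alternation turn: [t_start, t_end) held by oscillator ``active``."""

    t_start: float
    t_end: float
    active: int


@dataclass
class TurnTakingRun:
    """Result of a coupled turn-taking simulation."""

    traj1: Trajectory
    traj2: Trajectory
    turns: list[Turn] = field(default_factory=list)
    tl: float = 0.0


#: Starting amplitude of the joiner: it begins near rest and is spun up
#: by the initiator's transmitted activity during the first turn, so it
#: enters its first active turn already carrying the latency-shaped lag.
JOINER_INIT_MAGNITUDE = 0.1


def integrate_turn_taking(
    params1: OscillatorParams,
    params2: OscillatorParams,
    tl: float,
    duration: float,
    dt: float = DEFAULT_DT,
    init_phase: tuple[float, float] = (0.0, 0.0),
    init_magnitude: tuple[float, float] = (1.0, JOINER_INIT_MAGNITUDE),
    literal_joiner_sign: bool = False,
    max_turn_periods: float = 3.0,
) -> TurnTakingRun:
    """Two oscillators alternating active/passive roles with a transmission latency.

    There is no external carrier.  Oscillator 1 (the initiator) starts
    active; during a turn the active oscillator receives its own
    instantaneous activity scaled by its A coefficient, while the passive
    one receives the active oscillator's state delayed by the transmission
    latency ``tl`` (coefficient 1).  A turn ends when the active
    oscillator's unwrapped phase has advanced by a full cycle since the
    turn began; roles then swap.

    A positive frequency detuning (``params.delta``) is applied while an
    oscillator is in the passive (listening) role: the follower runs
    slightly fast relative to the oscillator driving it, compensating the
    incoming transmission and letting it complete cycles ahead of its
    driver.  Applied to both roles at once a common detuning would cancel
    out of the relative timing entirely.

    ``literal_joiner_sign`` flips the sign of oscillator 2's own-turn
    self-input coefficient (to -A), an alternative reading of the task in
    which the joiner's self-feedback is written with the opposite sign.
    By default both oscillators use the same coefficient A, preserving
    role symmetry.
    """
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    n_steps = int(round(duration / dt))
    tau1 = _snap_steps(params1.tau, dt)
    tau2 = _snap_steps(params2.tau, dt)
    tl_steps = _snap_steps(tl, dt)
    z10 = _init_state(init_phase[0], init_magnitude[0])
    z20 = _init_state(init_phase[1], init_magnitude[1])

    hist1 = max(tau1, tl_steps)
    hist2 = max(tau2, tl_steps)
    zs1: list[complex] = [z10] * (hist1 + 1)
    zs2: list[complex] = [z20] * (hist2 + 1)
    cur1, cur2 = hist1, hist2
    half = 0.5 * dt
    sixth = dt / 6.0
    A1 = params1.A
    A2 = -params2.A if literal_joiner_sign else params2.A

    # Detuning acts on the listening role only.
    from dataclasses import replace as _replace

    p1_active = _replace(params1, delta=0.0) if params1.delta else params1
    p2_active = _replace(params2, delta=0.0) if params2.delta else params2
    p1_passive, p2_passive = params1, params2

    active = 0  # oscillator 1 initiates
    turns: list[Turn] = []
    turn_start = 0.0
    phase_acc = 0.0  # unwrapped phase advance of the active oscillator this turn
    prev_angle = math.atan2(z10.imag, z10.real)
    max_turn_s = max_turn_periods / min(params1.effective_f, params2.effective_f)

    def interp(zs, cur, lag_steps, off):
        x = cur + off - lag_steps
        i = int(x)
        frac = x - i
        if frac == 0.0:
            return zs[i]
        return zs[i] + (zs[i + 1] - zs[i]) * frac

    for i in range(n_steps):
        t = i * dt
        z1, z2 = zs1[cur1], zs2[cur2]

        def rhs(ts, z1s, z2s, off):
            d1 = interp(zs1, cur1, tau1, off) if tau1 else z1s
            d2 = interp(zs2, cur2, tau2, off) if tau2 else z2s
            if active == 0:
                F1 = A1 * z1s
                F2 = interp(zs1, cur1, tl_steps, off) if tl_steps else z1s
                p1, p2 = p1_active, p2_passive
            else:
                F2 = A2 * z2s
                F1 = interp(zs2, cur2, tl_steps, off) if tl_steps else z2s
                p1, p2 = p1_passive, p2_active
            return (
                sappa_derivative(z1s, d1, F1, p1),
                sappa_derivative(z2s, d2, F2, p2),
            )

        a1, a2 = rhs(t, z1, z2, 0.0)
        b1, b2 = rhs(t + half, z1 + half * a1, z2 + half * a2, 0.5)
        c1, c2 = rhs(t + half, z1 + half * b1, z2 + half * b2, 0.5)
        e1, e2 = rhs(t + dt, z1 + dt * c1, z2 + dt * c2, 1.0)
        z1n = z1 + sixth * (a1 + 2.0 * (b1 + c1) + e1)
        z2n = z2 + sixth * (a2 + 2.0 * (b2 + c2) + e2)
        t_new = t + dt
        _check_finite(z1n, t_new)
        _check_finite(z2n, t_new)
        zs1.append(z1n)
        zs2.append(z2n)
        cur1 += 1
        cur2 += 1

        # Track the active oscillator's unwrapped phase to detect turn ends.
        za = z1n if active == 0 else z2n
        ang = math.atan2(za.imag, za.real)
        dang = ang - prev_angle
        if dang > math.pi:
            dang -= core.TWO_PI
        elif dang < -math.pi:
            dang += core.TWO_PI
        phase_acc += dang
        prev_angle = ang

        if phase_acc >= core.TWO_PI:
            turns.append(Turn(t_start=turn_start, t_end=t_new, active=active))
            active = 1 - active
            turn_start = t_new
            phase_acc = 0.0
            zb = z1n if active == 0 else z2n
            prev_angle = math.atan2(zb.imag, zb.real)
        elif t_new - turn_start > max_turn_s:
            raise TurnLockupError(
                f"active oscillator {active + 1} made no full cycle within "
                f"{max_turn_s:.2f} s after t = {turn_start:.3f} s"
            )

    # Close the final (possibly partial) turn so claps can be attributed.
    if duration > turn_start:
        turns.append(Turn(t_start=turn_start, t_end=duration, active=active))

    times = np.arange(n_steps + 1) * dt
    spec_free = StimulusSpec(kind=StimulusKind.NONE, fs=max(params1.f, 1e-9), feedback_mode=FeedbackMode.TURN_TAKING, tl=tl)
    z1_arr = np.asarray(zs1[hist1:], dtype=complex)
    z2_arr = np.asarray(zs2[hist2:], dtype=complex)
    empty_F = np.zeros(n_steps + 1, dtype=complex)
    run = TurnTakingRun(
        traj1=Trajectory(times=times, z=z1_arr, F=empty_F.copy(), params=params1, spec=spec_free, dt=dt),
        traj2=Trajectory(times=times, z=z2_arr, F=empty_F, params=params2, spec=spec_free, dt=dt),
        turns=turns,
        tl=tl,
    )
    return run
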