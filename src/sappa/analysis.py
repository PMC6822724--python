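"""Parameter-space analysis: (D, tau) asynchrony matrices, grid-search
fitting of the anticipation-vs-IOI curve, and attractor classification.

The sweep drives the oscillator with the unit sinusoid combined with
A times its own activity (which reduces to the plain sinusoid when A = 0)
and records one steady-state mean asynchrony per (D, tau) cell; cells
where the oscillator never settles to a constant phase relationship —
mode-locking or divergence — are flagged as failed rather than given a
number.

Attractor classification distinguishes the two long-run behaviors of the
stimulus-relative phase: convergence to a point (phase-locked, a fixed
point of the relative phase) versus persistent traversal of a closed loop
(mode-locking, a relative-phase limit cycle).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeedbackMode, OscillatorParams, StimulusKind, StimulusSpec
from .errors import ConfigError, MeasurementError, NoFitError, SappaError
from .integrator import DEFAULT_DT, integrate
from .measure import trajectory_asynchrony

#: Default sweep grids: D step 0.05 on [0, 1]; 27 tau points on [0, 0.5] s
#: (step 0.0185 s, placing the fitted value 0.222 s exactly on the grid).
DEFAULT_D_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
DEFAULT_TAU_GRID = tuple(np.round(np.linspace(0.0, 0.5, 27), 10))
DEFAULT_A_VALUES = (-1.0, -0.5, 0.0, 0.5, 1.0)

#: Relative-phase range (rad) over the terminal cycles above which a run
#: is classified as a limit cycle rather than a fixed point.
LIMIT_CYCLE_PHASE_RANGE = 0.1


def _sweep_spec(A: float, f: float) -> StimulusSpec:
    mode = FeedbackMode.OFF if A == 0.0 else FeedbackMode.CONSTANT_SELF
    return StimulusSpec(kind=StimulusKind.SINUSOID, fs=f, feedback_mode=mode)


def cell_asynchrony(
    D: float,
    tau: float,
    A: float,
    f: float,
    dt: float = DEFAULT_DT,
    n_cycles: int = 16,
) -> tuple[float, bool]:
    """Steady-state mean asynchrony (ms) for one parameter cell.

    Returns ``(asynchrony_ms, failed)``; a failed cell (no synchronization
    or integration blow-up) carries NaN.
    """
    params = OscillatorParams(f=f, D=D, tau=tau, A=A)
    spec = _sweep_spec(A, f)
    try:
        traj = integrate(params, spec, duration=n_cycles / f, dt=dt)
        series = trajectory_asynchrony(traj, mode="peak")
    except SappaError:
        return math.nan, True
    if not series.synchronized:
        return math.nan, True
    return series.mean_ms, False


@dataclass
class SweepResult:
    """Asynchrony (ms) and failure mask over a (D, tau) grid at fixed A, f."""

    A: float
    f: float
    D_grid: np.ndarray
    tau_grid: np.ndarray
    asynchrony_ms: np.ndarray  # shape (len(D_grid), len(tau_grid))
    failed: np.ndarray  # boolean, same shape

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, D in enumerate(self.D_grid):
            for j, tau in enumerate(self.tau_grid):
                rows.append(
                    dict(
                        A=self.A,
                        f_hz=self.f,
                        D=float(D),
                        tau_s=float(tau),
                        asynchrony_ms=float(self.asynchrony_ms[i, j]),
                        failed=bool(self.failed[i, j]),
                    )
                )
        return pd.DataFrame(rows)

    def to_matrix_frame(self, round_ms: bool = True) -> pd.DataFrame:
        """Matrix layout (rows D, columns tau), asynchrony rounded to whole ms."""
        vals = np.round(self.asynchrony_ms) if round_ms else self.asynchrony_ms
        return pd.DataFrame(
            vals,
            index=pd.Index(self.D_grid, name="D"),
            columns=pd.Index(self.tau_grid, name="tau_s"),
        )


def sweep_asynchrony_matrix(
    A: float,
    f: float = 1.0,
    D_grid=DEFAULT_D_GRID,
    tau_grid=DEFAULT_TAU_GRID,
    dt: float = DEFAULT_DT,
    n_cycles: int = 16,
) -> SweepResult:
    """Steady-state asynchrony over a (D, tau) grid for fixed A and f.

    Every cell is an independent integrate-and-measure run with identical
    settings — there are no sweep-specific shortcuts, so any single cell
    can be reproduced standalone.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if D_grid.size == 0 or tau_grid.size == 0:
        raise ConfigError("sweep grids must be non-empty")
    asym = np.full((len(D_grid), len(tau_grid)), math.nan)
    failed = np.zeros((len(D_grid), len(tau_grid)), dtype=bool)
    for i, D in enumerate(D_grid):
        for j, tau in enumerate(tau_grid):
            asym[i, j], failed[i, j] = cell_asynchrony(
                float(D), float(tau), A, f, dt=dt, n_cycles=n_cycles
            )
    return SweepResult(
        A=A, f=f, D_grid=D_grid, tau_grid=tau_grid, asynchrony_ms=asym, failed=failed
    )


def simulate_asynchrony_curve(
    D: float,
    tau: float,
    A: float,
    ioi_list_ms,
    dt: float = DEFAULT_DT,
    n_cycles: int = 16,
) -> np.ndarray:
    """Mean asynchrony (ms) at each IOI for one (D, tau, A); NaN where unsynchronized."""
    out = np.full(len(ioi_list_ms), math.nan)
    for k, ioi_ms in enumerate(ioi_list_ms):
        f = 1000.0 / float(ioi_ms)
        val, bad = cell_asynchrony(D, tau, A, f, dt=dt, n_cycles=n_cycles)
        if not bad:
            out[k] = val
    return out


@dataclass
class FitResult:
    """Outcome of the exhaustive grid search against a target regression line."""

    best_D: float
    best_tau: float
    best_A: float
    objective: float
    objectives: pd.DataFrame = field(repr=False, default=None)


def fit_parameters(
    target_slope: float,
    target_intercept: float,
    ioi_list_ms,
    D_grid,
    tau_grid,
    A_grid,
    dt: float = DEFAULT_DT,
    n_cycles: int = 16,
) -> FitResult:
    """Exhaustive grid search matching simulated anticipation to a target line.

    The target line gives the asynchrony in ms as a function of the IOI in
    ms (slope in ms per ms, intercept in ms).  The objective is the sum of
    squared deviations between the simulated asynchrony-vs-IOI points and
    the line; candidates with any unsynchronized IOI are excluded.  Ties
    break toward the smallest D, then the smallest tau, then the A closest
    to zero.
    """
    D_grid = list(D_grid)
    tau_grid = list(tau_grid)
    A_grid = list(A_grid)
    if not D_grid or not tau_grid or not A_grid:
        raise ConfigError("fit grids must be non-empty")
    if len(ioi_list_ms) == 0:
        raise ConfigError("at least one IOI is required for fitting")

    target = target_slope * np.asarray(ioi_list_ms, dtype=float) + target_intercept
    records = []
    best = None
    best_key = None
    for A in A_grid:
        for tau in tau_grid:
            for D in D_grid:
                curve = simulate_asynchrony_curve(
                    D, tau, A, ioi_list_ms, dt=dt, n_cycles=n_cycles
                )
                if np.any(np.isnan(curve)):
                    records.append(dict(D=D, tau_s=tau, A=A, objective=math.nan, failed=True))
                    continue
                obj = float(np.sum((curve - target) ** 2))
                records.append(dict(D=D, tau_s=tau, A=A, objective=obj, failed=False))
                key = (obj, D, tau, abs(A))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (D, tau, A, obj)
    if best is None:
        raise NoFitError("every grid candidate failed to synchronize")
    D, tau, A, obj = best
    return FitResult(
        best_D=float(D),
        best_tau=float(tau),
        best_A=float(A),
        objective=obj,
        objectives=pd.DataFrame(records),
    )


@dataclass
class AttractorResult:
    """Verdict of the relative-phase attractor classification."""

    verdict: str  # "fixed_point" or "limit_cycle"
    terminal_phases: np.ndarray
    multistable: bool = False


def _wrap(angles: np.ndarray) -> np.ndarray:
    return np.angle(np.exp(1j * angles))


def _circular_range(angles: np.ndarray) -> float:
    """Max angular spread of a set of angles around their circular mean."""
    mean = np.angle(np.mean(np.exp(1j * angles)))
    dev = _wrap(angles - mean)
    return float(dev.max() - dev.min())


def classify_attractor(
    params: OscillatorParams,
    spec: StimulusSpec,
    initial_phases=None,
    duration: float = 25.0,
    dt: float = DEFAULT_DT,
    terminal_cycles: int = 10,
) -> AttractorResult:
    """Classify the long-run stimulus-relative phase dynamics.

    Integrates from each initial phase and inspects the relative phase
    angle(z) - 2*pi*fs*t over the final ``terminal_cycles`` stimulus
    cycles.  If every run's relative phase collapses to a point (circular
    range below 0.1 rad) the attractor is a fixed point; if the relative
    phase keeps traversing a loop it is a limit cycle.  Mixed verdicts are
    reported as a limit cycle with a multistability warning.
    """
    if initial_phases is None:
        initial_phases = np.linspace(0.0, 2.0 * math.pi, 8, endpoint=False)
    initial_phases = np.asarray(initial_phases, dtype=float)
    if len(initial_phases) < 1:
        raise ConfigError("at least one initial phase is required")

    fs = spec.fs
    verdicts = []
    terminal = []
    for phi0 in initial_phases:
        try:
            traj = integrate(params, spec, duration=duration, dt=dt, init_phase=float(phi0))
        except SappaError:
            verdicts.append("limit_cycle")
            terminal.append(math.nan)
            continue
        rel = np.angle(traj.z) - 2.0 * math.pi * fs * traj.times
        tail = traj.times >= (duration - terminal_cycles / fs)
        spread = _circular_range(rel[tail])
        verdicts.append("fixed_point" if spread < LIMIT_CYCLE_PHASE_RANGE else "limit_cycle")
        terminal.append(float(_wrap(np.asarray([rel[-1]]))[0]))

    terminal = np.asarray(terminal)
    if all(v == "fixed_point" for v in verdicts):
        return AttractorResult(verdict="fixed_point", terminal_phases=terminal)
    multistable = any(v == "fixed_point" for v in verdicts)
    if multistable:
        warnings.warn(
            "mixed attractor verdicts across initial phases; reporting limit_cycle",
            stacklevel=2,
        )
    return AttractorResult(
        verdict="limit_cycle", terminal_phases=terminal, multistable=multistable
    )
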