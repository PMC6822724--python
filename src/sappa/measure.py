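"""Behavioral observables extracted from simulated trajectories.

Tapping experiments are scored on event times: the peaks of the real part
of the oscillator state stand in for taps/claps, and stimulus reference
events (peaks or valleys of the unit-sinusoid carrier) are known
analytically.  The per-cycle asynchrony is the model event time minus the
nearest stimulus reference time, so anticipation is negative — the sign
convention behind "negative mean asynchrony".

The turn-taking task is scored with a lead/lag statistic per turn:

    L = (a1 - b1) + (b2 - a2)

where a1/a2 are the first/last clap of the oscillator holding the turn and
b1/b2 the last clap of the previous holder / first clap of the next.  L in
ms is converted to a (signed) fraction of a 90 bpm beat as
``-90 * L_ms / 60000``; negative fractions mean the passive oscillator
lagged the active one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .errors import InsufficientTurnsError, MeasurementError

#: Steady state: every window of 5 consecutive asynchronies spans < 1 ms.
STEADY_WINDOW = 5
STEADY_RANGE_S = 1e-3
MIN_STEADY_CYCLES = 5

#: Conversion from L in ms to a fraction of a 90 bpm beat.
LEADLAG_FRACTION_PER_MS = -90.0 / 60000.0


def find_peaks(sig: np.ndarray, times: np.ndarray, min_distance_s: float = 0.0) -> np.ndarray:
    """Times of local maxima of a uniformly sampled signal.

    Interior local maxima are located by the sign change of the first
    difference and refined by fitting a parabola through the three samples
    around each maximum; endpoints are excluded.  A constant signal yields
    an empty array.  ``min_distance_s`` suppresses secondary maxima closer
    than that separation (input switching can put a shallow ripple on the
    oscillation crest); of competing maxima the tallest wins.
    """
    sig = np.asarray(sig, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(sig) < 3:
        return np.empty(0)
    if min_distance_s > 0.0:
        dt = times[1] - times[0]
        idx, _ = _signal.find_peaks(sig, distance=max(1, int(round(min_distance_s / dt))))
    else:
        idx, _ = _signal.find_peaks(sig)
    if len(idx) == 0:
        return np.empty(0)
    dt = times[1] - times[0]
    y0 = sig[idx - 1]
    y1 = sig[idx]
    y2 = sig[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = np.where(denom != 0.0, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    return times[idx] + shift * dt


def find_valleys(sig: np.ndarray, times: np.ndarray, min_distance_s: float = 0.0) -> np.ndarray:
    """Times of local minima (peaks of the negated signal)."""
    return find_peaks(-np.asarray(sig, dtype=float), times, min_distance_s=min_distance_s)


def cycle_completion_times(z: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Times at which the oscillator completes a cycle (phase crosses 2*pi*k).

    The unwrapped phase of ``z`` is interpolated linearly to the upward
    crossings of integer multiples of 2*pi.  For a steadily rotating
    oscillator these coincide with the peaks of Re(z); unlike raw peak
    detection they are insensitive to the amplitude ripple that switching
    inputs superimpose on the oscillation crest, which matters for
    clap-time bookkeeping in the turn-taking task.
    """
    phase = np.unwrap(np.angle(np.asarray(z)))
    times = np.asarray(times, dtype=float)
    k = phase / (2.0 * math.pi)
    k0 = math.floor(k[0]) + 1
    k1 = math.floor(k[-1])
    out = []
    idx = 0
    for target in range(k0, k1 + 1):
        idx = int(np.searchsorted(k[idx:], target)) + idx
        if idx == 0 or idx >= len(k):
            continue
        # Linear interpolation between the bracketing samples.
        t0, t1 = times[idx - 1], times[idx]
        f0, f1 = k[idx - 1], k[idx]
        out.append(t0 + (target - f0) / (f1 - f0) * (t1 - t0))
    return np.asarray(out)


def assess_synchrony(
    differences: np.ndarray,
    window: int = STEADY_WINDOW,
    range_tol_s: float = STEADY_RANGE_S,
    min_steady: int = MIN_STEADY_CYCLES,
) -> tuple[bool, int]:
    """Steady-state verdict for a per-cycle asynchrony series.

    The steady-state onset is the first index from which every window of
    ``window`` consecutive differences has range below ``range_tol_s``;
    the run counts as synchronized when such an onset exists and at least
    ``min_steady`` cycles follow it.  Drifting or mode-locked series never
    settle and return (False, len(differences)).
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < window + 1:
        return False, n
    # Rolling range over each window of `window` consecutive differences.
    sw = np.lib.stride_tricks.sliding_window_view(d, window)
    ranges = sw.max(axis=1) - sw.min(axis=1)
    bad = np.nonzero(ranges >= range_tol_s)[0]
    onset = 0 if len(bad) == 0 else int(bad[-1]) + 1
    if onset > len(ranges) - 1:
        return False, n
    synchronized = (n - onset) >= max(min_steady, window)
    return synchronized, onset


@dataclass
class AsynchronySeries:
    """Per-cycle model-minus-stimulus event-time differences and their summary."""

    ref_times: np.ndarray
    model_peak_times: np.ndarray
    differences_s: np.ndarray
    steady_onset_index: int
    synchronized: bool
    mean_ms: float
    sd_ms: float
    mode: str = "peak"

    @property
    def per_cycle(self) -> list[tuple[float, float, float]]:
        return list(zip(self.ref_times, self.model_peak_times, self.differences_s))


def stimulus_reference_times(
    fs: float, t_start: float, t_end: float, mode: str = "peak"
) -> np.ndarray:
    """Analytic peak (t = k/fs) or valley (t = (k+1/2)/fs) times of the carrier."""
    if mode not in ("peak", "valley"):
        raise MeasurementError(f"unknown reference mode {mode!r}")
    offset = 0.0 if mode == "peak" else 0.5
    k0 = math.ceil(t_start * fs - offset - 1e-9)
    k1 = math.floor(t_end * fs - offset + 1e-9)
    if k1 < k0:
        return np.empty(0)
    return (np.arange(k0, k1 + 1) + offset) / fs


def mean_asynchrony(
    model_peaks: np.ndarray,
    fs: float,
    t_start: float,
    t_end: float,
    mode: str = "peak",
    window: int = STEADY_WINDOW,
    range_tol_s: float = STEADY_RANGE_S,
    min_steady: int = MIN_STEADY_CYCLES,
) -> AsynchronySeries:
    """Pair each stimulus reference event with the nearest model peak.

    Reference events are the analytic peak (or, for anti-phase roles,
    valley) times of the unit carrier at frequency ``fs`` within
    [t_start, t_end].  The per-cycle difference is model peak time minus
    reference time; the mean and SD (in ms) are computed over the
    steady-state portion only and reported as NaN when the run never
    synchronizes.
    """
    model_peaks = np.asarray(model_peaks, dtype=float)
    if len(model_peaks) == 0:
        raise MeasurementError("no model peaks found; cannot measure asynchrony")
    refs = stimulus_reference_times(fs, t_start, t_end, mode=mode)
    if len(refs) == 0:
        raise MeasurementError("no stimulus reference events in the analysis window")

    pos = np.searchsorted(model_peaks, refs)
    left = np.clip(pos - 1, 0, len(model_peaks) - 1)
    right = np.clip(pos, 0, len(model_peaks) - 1)
    use_right = np.abs(model_peaks[right] - refs) < np.abs(model_peaks[left] - refs)
    nearest = np.where(use_right, model_peaks[right], model_peaks[left])
    diffs = nearest - refs

    synchronized, onset = assess_synchrony(
        diffs, window=window, range_tol_s=range_tol_s, min_steady=min_steady
    )
    if synchronized:
        steady = diffs[onset:]
        mean_ms = float(np.mean(steady) * 1e3)
        sd_ms = float(np.std(steady) * 1e3)
    else:
        mean_ms = math.nan
        sd_ms = math.nan
    return AsynchronySeries(
        ref_times=refs,
        model_peak_times=nearest,
        differences_s=diffs,
        steady_onset_index=onset,
        synchronized=synchronized,
        mean_ms=mean_ms,
        sd_ms=sd_ms,
        mode=mode,
    )


def trajectory_asynchrony(
    traj,
    mode: str = "peak",
    discard_s: float = 0.0,
    **kwargs,
) -> AsynchronySeries:
    """Convenience wrapper: Re(z) peaks of a trajectory vs its carrier events.

    Reference events are restricted to the span of the model peaks (plus a
    quarter-period margin) so edge events without a genuine nearby peak do
    not enter the series.
    """
    peaks = find_peaks(traj.z.real, traj.times, min_distance_s=0.5 / traj.spec.fs)
    peaks = peaks[peaks >= discard_s]
    if len(peaks) == 0:
        raise MeasurementError("no model peaks found after the discard window")
    margin = 0.25 / traj.spec.fs
    return mean_asynchrony(
        peaks,
        fs=traj.spec.fs,
        t_start=max(discard_s, float(peaks[0]) - margin),
        t_end=min(float(traj.times[-1]), float(peaks[-1]) + margin),
        mode=mode,
        **kwargs,
    )


@dataclass
class LeadLagResult:
    """Per-turn lead/lag values for one transmission latency."""

    tl_ms: float
    per_turn_L_s: np.ndarray
    per_turn_fraction: np.ndarray
    mean_fraction: float
    turn_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    slope_vs_tl: float | None = None

    @property
    def per_turn_percent(self) -> np.ndarray:
        return self.per_turn_fraction * 100.0


def leadlag_fraction(L_s: np.ndarray | float) -> np.ndarray | float:
    """Convert L (seconds) to the signed fraction of a 90 bpm beat."""
    return LEADLAG_FRACTION_PER_MS * np.asarray(L_s) * 1e3


def lead_lag(
    claps: tuple[np.ndarray, np.ndarray],
    turns,
    tl_ms: float = 0.0,
    skip_turns: int = 0,
) -> LeadLagResult:
    """Lead/lag statistic over the interior turns of a turn-taking run.

    ``claps`` holds the clap (Re(z) peak) times of oscillator 1 and 2;
    ``turns`` is the alternation schedule produced by the turn-taking
    integrator.  With one clap per oscillator cycle and one cycle per
    turn, each handover between turns is a seam where the outgoing
    oscillator's last clap and the incoming oscillator's first clap
    (nominally simultaneous) both occur.  For turn n: a1 and b1 are the
    turn-holder's and the previous holder's claps at the opening seam,
    a2 and b2 the holder's and the next holder's claps at the closing
    seam.  Claps are matched to a seam by nearest time, within half a
    turn; turns among the first ``skip_turns`` (transient) or with a
    missing event are skipped.
    """
    if len(turns) < 3:
        raise InsufficientTurnsError(
            f"lead/lag needs at least 3 turns, got {len(turns)}"
        )
    claps = (np.asarray(claps[0], dtype=float), np.asarray(claps[1], dtype=float))

    def nearest(model: int, t_seam: float, max_dist: float) -> float | None:
        c = claps[model]
        if len(c) == 0:
            return None
        i = int(np.argmin(np.abs(c - t_seam)))
        if abs(c[i] - t_seam) > max_dist:
            return None
        return float(c[i])

    L_vals: list[float] = []
    indices: list[int] = []
    for n in range(max(1, skip_turns), len(turns) - 1):
        cur = turns[n]
        other = turns[n - 1].active
        half_turn = 0.5 * (cur.t_end - cur.t_start)
        a1 = nearest(cur.active, cur.t_start, half_turn)
        b1 = nearest(other, cur.t_start, half_turn)
        a2 = nearest(cur.active, cur.t_end, half_turn)
        b2 = nearest(turns[n + 1].active, cur.t_end, half_turn)
        if None in (a1, b1, a2, b2):
            continue
        L_vals.append((a1 - b1) + (b2 - a2))
        indices.append(n)
    if not L_vals:
        raise InsufficientTurnsError("no interior turn had claps on both neighbors")
    L_arr = np.asarray(L_vals)
    frac = leadlag_fraction(L_arr)
    return LeadLagResult(
        tl_ms=tl_ms,
        per_turn_L_s=L_arr,
        per_turn_fraction=frac,
        mean_fraction=float(np.mean(frac)),
        turn_indices=np.asarray(indices, dtype=int),
    )
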