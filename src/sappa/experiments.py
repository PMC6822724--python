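"""End-to-end drivers for the three simulated synchronization tasks.

* Experiment 1 — solo metronome tapping across inter-onset intervals
  (IOIs) of 1000–3500 ms, with or without hearing one's own taps
  (constant self-input combined with the sinusoid vs sinusoid only).
* Experiment 2 — alternating paced tapping at 1 Hz: solo (self-input
  during the second half of every stimulus cycle) and duet (two
  oscillators, one in-phase and one anti-phase with the metronome,
  sharing each other's activity in alternating half-cycles).
* Experiment 3 — rhythm alternation without a metronome: two oscillators
  at 1.5 Hz (90 bpm) take turns driving each other across a fixed
  transmission latency; scored with the per-turn lead/lag statistic.

All drivers are deterministic and return tidy pandas tables alongside the
underlying measurement objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    FeedbackMode,
    OscillatorParams,
    StimulusKind,
    StimulusSpec,
    profile_params,
)
from .integrator import (
    DEFAULT_DT,
    TurnTakingRun,
    integrate,
    integrate_pair,
    integrate_turn_taking,
)
from .measure import (
    AsynchronySeries,
    LeadLagResult,
    cycle_completion_times,
    lead_lag,
    trajectory_asynchrony,
)

#: Metronome periods (ms) of the solo tapping task.
EXP1_IOIS_MS = (1000, 1250, 1500, 1750, 2000, 2250, 2500, 2750, 3000, 3250, 3500)
#: Transmission latencies (ms) probed in the turn-taking task.
EXP3_TLS_MS = (0.0, 10.0, 20.0, 39.0, 58.0, 78.0)
#: Oscillator frequency of the turn-taking task: 1.5 Hz = 90 bpm.
EXP3_F_HZ = 1.5
EXP3_DURATION_S = 30.0
#: Stimulus cycles simulated per condition (steady state plus margin).
DEFAULT_N_CYCLES = 16
#: Alternation turns discarded as transient before lead/lag statistics.
EXP3_SKIP_TURNS = 4


def _asynchrony_row(series: AsynchronySeries, **extra) -> dict:
    row = dict(extra)
    row.update(
        mean_asynchrony_ms=series.mean_ms,
        sd_ms=series.sd_ms,
        synchronized=series.synchronized,
    )
    return row


def run_experiment1(
    profile: str = "musician",
    feedback: bool = True,
    ioi_list_ms=EXP1_IOIS_MS,
    dt: float = DEFAULT_DT,
    n_cycles: int = DEFAULT_N_CYCLES,
) -> tuple[pd.DataFrame, list[AsynchronySeries]]:
    """Solo tapping across metronome periods.

    With feedback on, the input is the normalized combination of the unit
    sinusoid and A times the oscillator's instantaneous state; with
    feedback off, the sinusoid alone.  One steady-state mean asynchrony is
    reported per IOI; rows that never synchronize are flagged rather than
    dropped.
    """
    rows = []
    series_list = []
    for ioi_ms in ioi_list_ms:
        fs = 1000.0 / float(ioi_ms)
        params = profile_params(profile, f=fs)
        spec = StimulusSpec(
            kind=StimulusKind.SINUSOID,
            fs=fs,
            feedback_mode=FeedbackMode.CONSTANT_SELF if feedback else FeedbackMode.OFF,
        )
        traj = integrate(params, spec, duration=n_cycles / fs, dt=dt)
        series = trajectory_asynchrony(traj, mode="peak")
        series_list.append(series)
        rows.append(
            _asynchrony_row(
                series,
                profile=profile,
                feedback="on" if feedback else "off",
                ioi_ms=float(ioi_ms),
            )
        )
    return pd.DataFrame(rows), series_list


def run_experiment2_solo(
    profile: str = "musician",
    feedback: bool = True,
    duration: float = 20.0,
    dt: float = DEFAULT_DT,
    normalize: bool = True,
    return_trajectory: bool = False,
):
    """Solo alternating tapping at 1 Hz.

    Feedback-on adds the oscillator's own activity to the input during the
    second half of every stimulus cycle; feedback-off is the plain
    sinusoid throughout.  Returns the asynchrony series, plus the full
    trajectory when ``return_trajectory`` is set.
    """
    params = profile_params(profile, f=1.0)
    spec = StimulusSpec(
        kind=StimulusKind.SINUSOID,
        fs=1.0,
        feedback_mode=FeedbackMode.HALF_CYCLE_SELF if feedback else FeedbackMode.OFF,
        normalize=normalize,
    )
    traj = integrate(params, spec, duration=duration, dt=dt)
    series = trajectory_asynchrony(traj, mode="peak")
    if return_trajectory:
        return series, traj
    return series


def run_experiment2_duet(
    profile: str = "musician",
    feedback: bool = True,
    duration: float = 20.0,
    dt: float = DEFAULT_DT,
    normalize: bool = True,
    literal_partner_sign: bool = False,
) -> tuple[AsynchronySeries, AsynchronySeries]:
    """Duet alternating tapping at 1 Hz.

    Oscillator 1 synchronizes in phase with the sinusoid and oscillator 2
    anti-phase (negated carrier).  With feedback on, both receive the
    activity of one oscillator at a time, the source toggling twice per
    stimulus period.  Oscillator 1 is scored against stimulus peaks,
    oscillator 2 against stimulus valleys.
    """
    params = profile_params(profile, f=1.0)
    mode = FeedbackMode.DUET_ALTERNATING if feedback else FeedbackMode.OFF
    spec1 = StimulusSpec(
        kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=mode,
        normalize=normalize, literal_partner_sign=literal_partner_sign,
    )
    spec2 = StimulusSpec(
        kind=StimulusKind.ANTIPHASE_SINUSOID, fs=1.0, feedback_mode=mode,
        normalize=normalize, literal_partner_sign=literal_partner_sign,
    )
    traj1, traj2 = integrate_pair(params, params, spec1, spec2, duration=duration, dt=dt)
    series1 = trajectory_asynchrony(traj1, mode="peak")
    series2 = trajectory_asynchrony(traj2, mode="valley")
    return series1, series2


def experiment2_table(
    profile: str = "musician",
    duration: float = 20.0,
    dt: float = DEFAULT_DT,
) -> pd.DataFrame:
    """Solo and duet asynchronies for both feedback conditions, one profile."""
    rows = []
    for feedback in (True, False):
        fb = "on" if feedback else "off"
        solo = run_experiment2_solo(profile, feedback=feedback, duration=duration, dt=dt)
        rows.append(_asynchrony_row(solo, profile=profile, task="solo", role="solo", feedback=fb))
        duet1, duet2 = run_experiment2_duet(profile, feedback=feedback, duration=duration, dt=dt)
        rows.append(_asynchrony_row(duet1, profile=profile, task="duet", role="in_phase", feedback=fb))
        rows.append(_asynchrony_row(duet2, profile=profile, task="duet", role="anti_phase", feedback=fb))
    return pd.DataFrame(rows)


@dataclass
class Experiment3Result:
    """Lead/lag results across transmission latencies plus the fitted slope."""

    per_tl: list[LeadLagResult]
    table: pd.DataFrame
    slope_per_ms: float
    intercept: float
    runs: list[TurnTakingRun] = field(default_factory=list)


def run_experiment3(
    profile: str = "musician",
    tl_list_ms=EXP3_TLS_MS,
    duration: float = EXP3_DURATION_S,
    dt: float = DEFAULT_DT,
    delta_hz: float = 0.0,
    skip_turns: int = EXP3_SKIP_TURNS,
    literal_joiner_sign: bool = False,
    keep_runs: bool = False,
) -> Experiment3Result:
    """Turn-taking rhythm alternation across transmission latencies.

    Two identical oscillators at 1.5 Hz alternate active/passive roles;
    the passive one hears the active one's activity delayed by the
    transmission latency.  Per latency, the mean lead/lag fraction of a
    90 bpm beat is reported, followed by the least-squares slope of the
    mean fraction against latency.  A positive frequency detuning
    ``delta_hz`` makes an oscillator run slightly fast while in the
    listening (passive) role — compensating the incoming transmission the
    way performers compensate sound travel — which shifts the lead/lag
    curve upward and produces positive fractions at small latencies.
    """
    params = profile_params(profile, f=EXP3_F_HZ, delta=delta_hz)
    per_tl: list[LeadLagResult] = []
    runs: list[TurnTakingRun] = []
    rows = []
    for tl_ms in tl_list_ms:
        run = integrate_turn_taking(
            params,
            params,
            tl=tl_ms * 1e-3,
            duration=duration,
            dt=dt,
            literal_joiner_sign=literal_joiner_sign,
        )
        claps = (
            cycle_completion_times(run.traj1.z, run.traj1.times),
            cycle_completion_times(run.traj2.z, run.traj2.times),
        )
        result = lead_lag(claps, run.turns, tl_ms=float(tl_ms), skip_turns=skip_turns)
        per_tl.append(result)
        if keep_runs:
            runs.append(run)
        rows.append(
            dict(
                tl_ms=float(tl_ms),
                n_turns=len(result.per_turn_L_s),
                mean_L_ms=float(np.mean(result.per_turn_L_s) * 1e3),
                mean_fraction=result.mean_fraction,
                mean_percent=result.mean_fraction * 100.0,
            )
        )
    table = pd.DataFrame(rows)
    slope, intercept = np.polyfit(table["tl_ms"], table["mean_fraction"], 1)
    for r in per_tl:
        r.slope_vs_tl = float(slope)
    return Experiment3Result(
        per_tl=per_tl,
        table=table,
        slope_per_ms=float(slope),
        intercept=float(intercept),
        runs=runs,
    )


def leadlag_long_table(result: Experiment3Result) -> pd.DataFrame:
    """Per-turn lead/lag table (tl_ms, turn, L_ms, fraction, percent)."""
    rows = []
    for r in result.per_tl:
        for turn, L, frac in zip(r.turn_indices, r.per_turn_L_s, r.per_turn_fraction):
            rows.append(
                dict(
                    tl_ms=r.tl_ms,
                    turn=int(turn),
                    L_ms=L * 1e3,
                    fraction=frac,
                    percent=frac * 100.0,
                )
            )
    return pd.DataFrame(rows)
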