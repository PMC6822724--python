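# Methods

## Model

The simulated unit is a canonical Hopf oscillator with delayed recurrent
feedback. In the form integrated by the package,

    dz/dt = (f + Δ) · [ z (α + i2π + β₁|z|² + εβ₂|z|⁴ / (1 − ε|z|²)) + F ]
            − D · z(t − τ)

The general parameterization (β₂, ε) is exposed for completeness; every
simulated task uses the reduced setting α = 1, β₁ = −1, β₂ = ε = 0, for
which the unforced, delay-free oscillator has an attracting limit cycle of
unit magnitude rotating at f Hz. The delayed term −(D/f)·z(t−τ) (written
above multiplied through by the frequency) feeds the oscillator's own past
state back with amplitude D after τ seconds; with a periodic drive it
shifts the entrained phase forward, producing the anticipatory (negative)
asynchrony that is the model's point. Because the term carries D/f, its
effective strength grows as the stimulus slows, which is what makes
anticipation grow with the metronome period.

Parameters, units, defaults:

| parameter | meaning | default |
|---|---|---|
| α, β₁ | radial dynamics | 1, −1 (fixed in all tasks) |
| f | natural frequency, Hz | task-dependent; always equal to the stimulus frequency f_s |
| D | delayed-feedback amplitude, ≥0 | 0.05 (musician) / 0.36 (non-musician) |
| τ | feedback delay, s | 0.222 |
| A | coefficient on instantaneous self/partner activity | −0.5 |
| Δ | frequency detuning, Hz | 0 |

The two performer profiles differ **only** in D.

## Inputs

- **Metronome**: F = exp(i2πf_s t); the anti-phase role uses the negated
  carrier; a square-wave variant sign(cos 2πf_s t) is peak-aligned with the
  sinusoid so asynchrony measurements are comparable.
- **Hearing oneself**: F = (exp(i2πf_s t) + A z)/|exp(i2πf_s t) + A z|.
  The unit-magnitude normalization is applied whenever a carrier is
  combined with oscillator activity (the alternating-tapping drivers expose
  `normalize` for the unnormalized reading). The zero-denominator point
  raises a degenerate-input error.
- **Half-cycle feedback** (alternating tapping): the combined form is used
  during the second half of every stimulus cycle, the bare carrier during
  the first half. The boundary is defined on the carrier's phase — it is
  the only clock the two forms share.
- **Duet alternation**: both oscillators receive A·z(k), with k toggling
  between the two oscillators twice per stimulus period, starting with
  each model's own state. A single sign convention is used — the
  coefficient A (itself negative) multiplies every instantaneous-activity
  term; a `literal_partner_sign` flag flips the partner term's sign for
  the alternative reading. Both conventions reproduce the feedback-on <
  feedback-off ordering.
- **Turn-taking** (no metronome): the active oscillator receives A·z_self;
  the passive one receives the active oscillator's state delayed by the
  transmission latency, coefficient 1. The latency applies only to the
  transmitted signal — one hears oneself instantly. Both oscillators use
  coefficient A for their own-turn input (role symmetry); a
  `literal_joiner_sign` flag gives the asymmetric reading.

## Integration

Delay differential equations are advanced with a classical 4th-order
Runge–Kutta step on a fixed grid (default dt = 1 ms). Delays (τ, TL) are
snapped to the nearest grid multiple (≤0.5 ms snap error, below the 1 ms
event-timing resolution of the measurements); history lookups at on-grid
times are exact, half-step stage lookups interpolate linearly between
samples. Pre-history (t < 0) is the constant initial state, the standard
convention for delay equations. Coupled pairs are stepped jointly as one
system so instantaneous partner terms enter through the Runge–Kutta stage
states rather than a lagged sample. Everything is deterministic; repeated
runs are byte-identical.

The linear delay interpolation caps the global order: step-halving shows
clean second-order convergence, and terminal states agree with an
independent adaptive method-of-steps integration (scipy DOP853 with dense
output, implemented in the test suite) to better than 1e-3 in modulus at
dt = 1 ms. Trajectories whose magnitude diverges raise a blow-up error
with the failure time.

Initialization: magnitude 1 at phase 0 (on the unforced limit cycle),
minimizing transient length. In the turn-taking task the joiner starts at
magnitude 0.1 and is spun up by the initiator's transmitted signal during
the first turn, reflecting a performer who listens before joining.

## Measurements

- **Asynchrony**: stimulus reference events are the analytic peak times
  k/f_s (or valley times (k+½)/f_s for the anti-phase role) of the unit
  carrier; each reference is paired with the nearest peak of Re z
  (quadratic sub-sample refinement of local maxima). The per-cycle
  difference is model minus stimulus, so anticipation is negative.
  Reference events are restricted to the span of the model peaks plus a
  quarter-period margin, so edge events with no genuine nearby peak are
  not scored.
- **Steady state**: the onset is the first index from which every window
  of 5 consecutive per-cycle differences spans < 1 ms; a run counts as
  synchronized when at least 5 cycles follow the onset. Mean and SD are
  computed over the post-onset cycles only and are undefined (NaN) for
  unsynchronized runs. The 1 ms / 5-cycle criterion is this package's
  choice and is exposed as configuration.
- **Claps** in the turn-taking task are the oscillator's cycle-completion
  times — the upward crossings of the unwrapped phase through multiples of
  2π. For steady rotation these coincide with Re z peaks, but they are
  insensitive to the amplitude ripple that switching inputs superimpose on
  the oscillation crest, which makes raw peak times snap between ripple
  lobes and corrupt per-turn bookkeeping.
- **Lead/lag**: a turn ends when the active oscillator's unwrapped phase
  has advanced 2π since the turn began (the oscillator's own cycle is the
  only intrinsic clock). For each interior turn,
  L = (a₁ − b₁) + (b₂ − a₂) over the claps matched (nearest in time,
  within half a turn) to the turn's opening and closing handover seams;
  the beat-fraction conversion is −90·L_ms/(60·1000), with a percent
  column (×100) for reporting. The first 4 turns are discarded as
  warm-up. 30-second trials do not fully relax — the pair's relative
  timing carries a slowly damped oscillation — so per-latency means
  wobble by a few tenths of a percent of the beat around the settled
  values (longer runs confirm the settled lag grows essentially linearly
  with the latency).
- **Detuning** (Δ > 0) in the turn-taking task is applied while an
  oscillator is in the listening (passive) role, making the follower run
  slightly fast relative to its driver — the mechanism by which performers
  compensate transmission delays. Applied to both roles at once a common
  detuning cancels out of the relative timing identically, so the
  symmetric reading cannot shift the lead/lag curve; the listening-role
  reading shifts it upward and yields leads (positive fractions) at small
  latencies.

## Parameter analysis

The sweep evaluates one independent integrate-and-measure run per (D, τ)
cell — 16 stimulus cycles by default, the same routine a standalone run
uses — and flags cells that fail the steady-state criterion instead of
reporting a number. Matrix outputs round to whole ms (full precision is
kept in the long-format table). Default grids: D in steps of 0.05 on
[0, 1]; 27 τ points on [0, 0.5] s so that 0.222 s lies on the grid;
A ∈ {−1, −0.5, 0, 0.5, 1}.

Grid-search fitting minimizes the summed squared deviation between the
simulated asynchrony-vs-IOI points and a user-supplied regression line
(slope in ms per ms of IOI, intercept in ms); candidates with any
unsynchronized IOI are excluded, and ties break toward smaller D, then
smaller τ, then A nearest zero. Recovery is exact when the target line is
generated by the model at an on-grid cell.

Attractor classification integrates from a grid of initial phases and
inspects the stimulus-relative phase over the final 10 cycles: circular
range < 0.1 rad in every run is a fixed point (phase locking); otherwise a
limit cycle (mode locking), with a multistability warning when verdicts
mix. The 0.1 rad threshold is a package choice.

## Problem sizes and defaults

Tapping runs simulate 16 stimulus cycles per condition (20 s at 1 Hz,
matching the alternating-tapping task's stated duration); turn-taking
trials run 30 s at 1.5 Hz; all at dt = 1 ms. These sizes put every
reported mean well past the steady-state onset while keeping full
experiment suites to seconds of compute.

## Limitations

- The model is deterministic: it reproduces mean anticipatory tendencies,
  not the variability, long-range fluctuations, or occasional positive
  asynchronies of human tapping. Passing tests demonstrate the dynamics'
  orderings, not distributional realism.
- The linear anticipation-vs-IOI picture holds in the 1000–3500 ms range;
  outside it the model's nonlinearities dominate and no claims are made.
- Turn-taking trials at 30 s retain slow transients (see above); summary
  values are windowed means, not fixed-point values.
- Networks larger than two oscillators, adaptive frequency, and noise
  extensions are out of scope.
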