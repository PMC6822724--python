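"""Parameter-space structure: asynchrony over (D, tau), attractors, recovery.

Sweeps the delayed-feedback amplitude D and delay tau on a coarse grid at
A = -0.5, f = 1 Hz, classifies the relative-phase attractor at a locked
and a mode-locked point, and demonstrates that the grid-search fit
recovers the parameters that generated a target anticipation line.
"""

import numpy as np

from sappa.analysis import (
    classify_attractor,
    fit_parameters,
    simulate_asynchrony_curve,
    sweep_asynchrony_matrix,
)
from sappa.core import FeedbackMode, OscillatorParams, StimulusKind, StimulusSpec

sweep = sweep_asynchrony_matrix(
    A=-0.5, f=1.0, D_grid=(0.0, 0.25, 0.5, 1.0), tau_grid=(0.0, 0.1, 0.222, 0.35, 0.5)
)
print("asynchrony (ms; NaN = did not synchronize), rows D, columns tau:")
print(sweep.to_matrix_frame())

spec = StimulusSpec(kind=StimulusKind.SINUSOID, fs=1.0, feedback_mode=FeedbackMode.CONSTANT_SELF)
locked = classify_attractor(OscillatorParams(f=1.0, D=1.0, tau=0.05, A=0.0),
                            StimulusSpec(kind=StimulusKind.SINUSOID, fs=1.0), duration=20.0)
modelocked = classify_attractor(OscillatorParams(f=1.0, D=1.0, tau=0.3, A=1.0), spec, duration=20.0)
print(f"\nattractor at D=1, tau=0.05, A=0:   {locked.verdict}")
print(f"attractor at D=1, tau=0.30, A=1:   {modelocked.verdict}")

iois = (1000, 1500, 2000)
curve = simulate_asynchrony_curve(0.36, 0.222, -0.5, iois)
slope, intercept = np.polyfit(iois, curve, 1)
fit = fit_parameters(slope, intercept, iois,
                     D_grid=(0.05, 0.36), tau_grid=(0.111, 0.222), A_grid=(-0.5,))
print(f"\ntarget line from (D=0.36, tau=0.222, A=-0.5): slope {slope:.4f} ms/ms")
print(f"recovered: D={fit.best_D}, tau={fit.best_tau}, A={fit.best_A} "
      f"(objective {fit.objective:.3f})")

print(
    "\nThe D=0 row is zero (no anticipation without delayed feedback); cells\n"
    "deep in the D=1 region fail to synchronize (mode-locking, a relative-\n"
    "phase limit cycle), and the exhaustive fit recovers the generating\n"
    "parameter cell exactly."
)
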