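"""Solo metronome tapping: anticipation grows with the metronome period.

Simulates the musician (D = 0.05) and non-musician (D = 0.36) oscillator
profiles tapping with metronomes of 1000-3500 ms period, with and without
hearing their own activity, and prints the steady-state mean asynchrony
(model peak time minus stimulus peak time, so negative = anticipation).
"""

import pandas as pd

from sappa.experiments import run_experiment1

iois = (1000, 1500, 2000, 2500, 3000, 3500)
tables = []
for profile in ("musician", "nonmusician"):
    for feedback in (True, False):
        table, _ = run_experiment1(profile=profile, feedback=feedback, ioi_list_ms=iois)
        tables.append(table)
result = pd.concat(tables, ignore_index=True)

print(result.round(2).to_string(index=False))
print(
    "\nEvery mean asynchrony is negative (taps precede the beat) and grows in\n"
    "magnitude with the metronome period; the non-musician profile (larger\n"
    "delayed-feedback amplitude D) anticipates more than the musician, and\n"
    "removing auditory feedback (feedback=off) increases anticipation further."
)
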