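"""Classify movement states and attribute the distance loss to them.

Tracks are re-discretised on a 5 min grid; step lengths and turning
angles feed a 3-state HMM (zero-inflated gamma steps, von Mises angles).
After Viterbi decoding, each grid cell's deviation rate — metres of real
travel discarded per minute — is grouped by state.
"""

import numpy as np

from trackthin import (
    SimulationConfig,
    fit_hmm,
    resample_time_regular,
    simulate_cohort,
    state_conditional_deviation,
    steps_and_angles,
    viterbi,
)

truth = simulate_cohort(SimulationConfig(n_tracks=20, seed=5))
series = [
    steps_and_angles(resample_time_regular(t, 300.0, include_terminal=False))
    for t in truth.tracks
]
params = fit_hmm(series, n_states=3, n_starts=5, seed=1)

print("state  mean_step_m  zero_mass  angle_kappa")
for i, s in enumerate(params.states, 1):
    print(f"{i:>5}  {s.step_mean:>11.1f}  {s.step_zero_mass:>9.3f}  {s.angle_kappa:>11.2f}")

rates, states = [], []
for t, s in zip(truth.tracks, series):
    dec = viterbi(params, s)
    _, r = state_conditional_deviation(t, 300.0, dec)
    rates.append(r)
    states.append(dec.states)
rates, states = np.concatenate(rates), np.concatenate(states)
for k in (1, 2, 3):
    print(f"state {k}: median deviation rate {np.median(rates[states == k]):.2f} m/min "
          f"({(states == k).sum()} cells)")
# State 1 (resting) loses nothing; the fast state loses the most metres
# per minute, because small turns cost more distance at high speed.
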