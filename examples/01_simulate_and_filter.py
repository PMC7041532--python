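"""Simulate a synthetic cohort of 2 h follows and apply the gap filter.

Builds 56 quasi-continuous tracks (irregular ~19 s fix cadence), injects
recording gaps > 60 s into 9 of them, and shows how the max-gap rule
partitions the cohort, plus the leg statistics of the retained tracks.
"""

import numpy as np

from trackthin import SimulationConfig, filter_by_max_gap, inject_gap, path_length, simulate_cohort

cfg = SimulationConfig(n_tracks=56, seed=42)
truth = simulate_cohort(cfg)
tracks = list(truth.tracks)

rng = np.random.default_rng(42)
for i in rng.choice(len(tracks), size=9, replace=False):
    tracks[i] = inject_gap(tracks[i], gap_s=90.0, position_s=float(rng.uniform(600, 6000)))

report = filter_by_max_gap(tracks, max_gap_s=60.0)
kept = [t for t in tracks if t.track_id in set(report.retained)]

legs = np.concatenate([np.diff(t.t) for t in kept])
dists = [path_length(t) for t in kept]
print(f"retained {len(report.retained)} tracks, excluded {len(report.excluded)} (gap > 60 s)")
print(f"leg time: mean {legs.mean():.1f} s, SD {legs.std():.1f} s, max {legs.max():.0f} s")
print(f"2 h distance: median {np.median(dists):.0f} m, range {min(dists):.0f}-{max(dists):.0f} m")
# The retained cohort mirrors a field campaign: ~2 h follows recorded at
# ~19 s cadence, with interrupted follows dropped before any analysis.
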