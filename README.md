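# trackthin

Quantify how time-interval subsampling of quasi-continuous GPS tracks
underestimates travel distance.

Daily travel distance (DTD) is a workhorse metric in movement ecology, but
GPS collars ration their battery by fixing positions at intervals of minutes
to hours. Because the recorded path is a chord-by-chord shortcut of the real
one, the estimated distance is biased low — the coarser the sampling, the
larger the shortfall. `trackthin` measures that bias from quasi-continuous
reference tracks (e.g. a researcher following an animal with a handheld GPS
at ~19 s cadence), models it as a function of the sampling interval, and
attributes it to movement states. It is aimed at field ecologists deciding
on a sampling protocol and at analysts correcting distance estimates after
the fact.

## What it computes

**Re-discretisation and deviation.** A track is resampled onto a regular
time grid (default 1, 2, 5, 10, 15, 30, 60, 90, 120 min) by linear
interpolation along the recorded polyline. The deviation at interval *t* is

  y = 100 · (L_orig − L_resampled) / L_orig  [%],

which is confined to [0, 100] % by the triangle inequality and is monotone
along nested grids.

**Deviation curve.** Deviations are modelled with a shifted log-normal mixed
regression: with c = −15,

  log(y − c) = β₀ + β₁·t + β₂·log t + γᵢ + ε,  γᵢ ~ N(0, τ²), ε ~ N(0, σ²),

with a random intercept γᵢ per track. Estimation is exact maximum marginal
likelihood (the Gaussian random intercept integrates out analytically);
the population expectation E[y|t] = c + exp(β₀ + β₁t + β₂log t + (σ²+τ²)/2)
is reported with a point-wise 99 % band. Leave-one-track-out predictive
density (or AIC) ranks alternative predictor sets.

**Movement states.** On a 5-min grid, step lengths and turning angles feed a
3-state hidden Markov model — zero-inflated gamma steps, von Mises turning
angles — fitted by direct maximum likelihood with multi-start
initialisation. Viterbi decoding labels each grid cell resting (1),
slow/tortuous (2) or fast/straight (3), and the deviation **rate** (metres
of real travel discarded per minute) is summarised per state.

**Synthetic cohorts.** A seeded generator produces 2 h tracks as 1 Hz
correlated random walks with three latent states and irregular fix cadence
(mean 18.8 s, SD 11 s, max 60 s), giving every pipeline stage a ground
truth to be tested against.

## Worked example

```python
import numpy as np
from trackthin import (SimulationConfig, simulate_cohort, deviation_table,
                       CurveModelSpec, fit_curve, expected_deviation)

truth = simulate_cohort(SimulationConfig(n_tracks=47, seed=11))
records = deviation_table(truth.tracks)
fit = fit_curve(records, CurveModelSpec(shift_c=-15.0, uncertainty_level=0.99))
print(np.round(fit.beta, 4))
print(expected_deviation(fit, np.array([1.0, 60.0, 120.0])))
```

prints (numbers from this exact seed):

```
[ 3.2474e+00 -2.8000e-03  3.2460e-01]
   interval_min  expected_pct  lower_pct  upper_pct
0           1.0     10.883205   9.809278  12.003618
1          60.0     68.017902  65.246306  70.885226
2         120.0     73.034501  69.257120  76.981228
```

Read: sampling this cohort once a minute already loses ~11 % of the true
distance; once an hour loses ~68 %, and doubling the interval to two hours
barely changes it (the curve rises steeply at short intervals and flattens
beyond ~1 h). The β vector lives on the log scale of the shifted response;
β₂ > 0 with β₁ ≈ 0 is the "exponential rise then levelling" shape.

The `examples/` directory holds one short script per capability
(simulation + gap filtering, deviation tables, the curve model, the HMM,
the full pipeline); each prints the numbers it computes and a line on how
to read them. A thin CLI mirrors the library: `trackthin simulate | ingest |
deviations | summarize | kw | curve | hmm | decode | state-deviation | run`.

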