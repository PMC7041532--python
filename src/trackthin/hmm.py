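"""Three-state movement HMM on regularly re-discretised tracks.

Observations per grid interval are the step length (displacement, metres)
and the signed turning angle between consecutive steps
(counter-clockwise positive, wrapped to (-pi, pi]).  Emissions follow the
standard movement-ecology convention: a zero-inflated gamma for steps (a
point mass at exactly zero lets a resting state emit no movement) and a
von Mises for turning angles, with angles adjacent to zero-length steps
treated as missing (likelihood 1).  Fitting is direct numerical
maximisation of the forward log-likelihood over an unconstrained
reparameterisation, with multi-start initialisation; decoding is the
Viterbi algorithm.  States are canonically ordered by ascending mean step
length, so state 1 is resting, state 2 slow/tortuous, state 3
fast/straight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, special

from .stats import BoxSummary, box_summary
from .trackio import LOCAL_METRIC, Track

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class StepAngleSeries:
    """Step lengths (length T) and turning angles (length T-1, NaN where
    a bounding step has zero length) for one track on a regular grid."""

    steps: np.ndarray
    angles: np.ndarray
    track_id: str = ""

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "steps", steps)
        object.__setattr__(self, "angles", angles)
        if angles.size != max(steps.size - 1, 0):
            raise ValueError("angles must have length len(steps) - 1")
        if np.any(steps < 0):
            raise ValueError("negative step length")
        defined = angles[~np.isnan(angles)]
        if defined.size and (np.any(defined <= -math.pi - 1e-12) or np.any(defined > math.pi + 1e-12)):
            raise ValueError("angles must lie in (-pi, pi]")

    @property
    def T(self) -> int:
        return int(self.steps.size)


@dataclass(frozen=True)
class StateModel:
    """Emission distributions of one movement state.

    Steps: point mass ``step_zero_mass`` at 0 mixed with a gamma of the
    given mean/SD (metres per grid interval).  Angles: von Mises with
    mean ``angle_mean`` (radians) and concentration ``angle_kappa``
    (kappa -> 0 is the uniform-turning limit).
    """

    step_zero_mass: float
    step_mean: float
    step_sd: float
    angle_mean: float = 0.0
    angle_kappa: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.step_zero_mass <= 1.0:
            raise ValueError("step_zero_mass must lie in [0, 1]")
        if self.step_mean <= 0 or self.step_sd <= 0:
            raise ValueError("step_mean and step_sd must be positive")
        if self.angle_kappa < 0:
            raise ValueError("angle_kappa must be non-negative")


@dataclass(frozen=True)
class HMMParameters:
    states: tuple[StateModel, ...]
    transition: np.ndarray  # row-stochastic
    initial: np.ndarray
    loglik: float | None = None  # attained log-likelihood when fitted

    def __post_init__(self) -> None:
        A = np.asarray(self.transition, dtype=float)
        pi0 = np.asarray(self.initial, dtype=float)
        object.__setattr__(self, "transition", A)
        object.__setattr__(self, "initial", pi0)
        n = len(self.states)
        if A.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1) > 1e-10):
            raise ValueError("transition rows must be non-negative and sum to 1")
        if pi0.shape != (n,) or np.any(pi0 < 0) or abs(pi0.sum() - 1) > 1e-10:
            raise ValueError("initial distribution must be a simplex vector")

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DecodedTrack:
    series: StepAngleSeries
    states: np.ndarray  # 1-based labels, length T

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=int)
        object.__setattr__(self, "states", s)
        if s.size != self.series.T:
            raise ValueError("states length must equal steps length")


# ---------------------------------------------------------------------------
# Observation preparation


def wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap radians to (-pi, pi]."""
    w = -((-np.asarray(a) + math.pi) % _TWO_PI - math.pi)
    return w


def steps_and_angles(resampled_track: Track, rel_tol: float = 1e-6) -> StepAngleSeries:
    """Extract step lengths and signed turning angles from a regular-grid track.

    The track must already be re-discretised on a regular grid (use
    ``resample_time_regular(..., include_terminal=False)``).  Angle i is
    the heading change from step i to step i+1, counter-clockwise
    positive; it is missing (NaN) when either bounding step has zero
    length, since a zero step has no heading.
    """
    if resampled_track.frame != LOCAL_METRIC:
        raise ValueError("steps_and_angles requires a local-metric track")
    if resampled_track.n_fixes < 3:
        raise ValueError("need at least 3 fixes (2 steps) for turning angles")
    dt = np.diff(resampled_track.t)
    if np.ptp(dt) > rel_tol * dt.mean():
        raise ValueError(
            "irregular time grid: re-discretise the track first "
            "(resample_time_regular with include_terminal=False)"
        )
    dx = np.diff(resampled_track.x)
    dy = np.diff(resampled_track.y)
    steps = np.hypot(dx, dy)
    headings = np.arctan2(dy, dx)
    angles = wrap_angle(np.diff(headings))
    zero = steps == 0.0
    angles[zero[:-1] | zero[1:]] = np.nan
    return StepAngleSeries(steps=steps, angles=angles, track_id=resampled_track.track_id)


# ---------------------------------------------------------------------------
# Likelihood machinery

_LOG_EPS = -745.0  # ~log of smallest positive double; stands in for log(0)


def _gamma_logpdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return (
        (shape - 1.0) * np.log(x)
        - x / scale
        - special.gammaln(shape)
        - shape * np.log(scale)
    )


def _vonmises_logpdf(a: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    # log I0(kappa) = log(i0e(kappa)) + kappa, overflow-safe
    return kappa * np.cos(a - mu) - math.log(_TWO_PI) - (np.log(special.i0e(kappa)) + kappa)


def _emission_logprob(params: HMMParameters, series: StepAngleSeries) -> np.ndarray:
    """T x n_states matrix of per-observation emission log-densities.

    Observation t couples step t with the turning angle into step t
    (angle t-1); the first step carries no angle, and missing angles
    contribute likelihood 1.
    """
    T, n = series.T, params.n_states
    logB = np.zeros((T, n))
    zero = series.steps == 0.0
    pos = ~zero
    for j, st in enumerate(params.states):
        col = np.empty(T)
        col[zero] = math.log(st.step_zero_mass) if st.step_zero_mass > 0 else _LOG_EPS
        if pos.any():
            lp = _gamma_logpdf(series.steps[pos], st.step_mean, st.step_sd)
            col[pos] = (
                math.log1p(-st.step_zero_mass) if st.step_zero_mass < 1 else _LOG_EPS
            ) + lp
        logB[:, j] = col
        if T > 1:
            ok = ~np.isnan(series.angles)
            if ok.any():
                la = _vonmises_logpdf(series.angles[ok], st.angle_mean, st.angle_kappa)
                idx = np.flatnonzero(ok) + 1  # angle t-1 belongs to observation t
                logB[idx, j] += la
    return logB


def _forward_logsumexp(log_init, logA, logB) -> float:
    alpha = log_init + logB[0]
    for t in range(1, logB.shape[0]):
        m = alpha.max()
        alpha = m + np.log(np.exp(alpha - m) @ np.exp(logA)) + logB[t]
    m = alpha.max()
    return float(m + np.log(np.exp(alpha - m).sum()))


def hmm_loglik(params: HMMParameters, series_list: Sequence[StepAngleSeries]) -> float:
    """Total forward log-likelihood, summed over tracks.

    Each track restarts the forward recursion from the initial
    distribution; computation is in log space, safe for long series.
    """
    if not series_list:
        raise ValueError("empty series list")
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition)
        log_init = np.log(params.initial)
    logA = np.nan_to_num(logA, neginf=_LOG_EPS)
    log_init = np.nan_to_num(log_init, neginf=_LOG_EPS)
    total = 0.0
    for s in series_list:
        logB = _emission_logprob(params, s)
        total += _forward_logsumexp(log_init, logA, logB)
    return total


def viterbi(params: HMMParameters, series: StepAngleSeries) -> DecodedTrack:
    """Most probable state path (1-based labels); ties break toward the
    lower state index."""
    with np.errstate(divide="ignore"):
        logA = np.nan_to_num(np.log(params.transition), neginf=_LOG_EPS)
        log_init = np.nan_to_num(np.log(params.initial), neginf=_LOG_EPS)
    logB = _emission_logprob(params, series)
    T, n = logB.shape
    delta = log_init + logB[0]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)  # first max -> lower index on ties
        delta = cand[back[t], np.arange(n)] + logB[t]
    states = np.empty(T, dtype=int)
    states[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return DecodedTrack(series=series, states=states + 1)


def viterbi_path_logprob(params: HMMParameters, series: StepAngleSeries) -> float:
    """Joint log-probability of the Viterbi path with the observations."""
    dec = viterbi(params, series)
    return path_logprob(params, series, dec.states)


def path_logprob(
    params: HMMParameters, series: StepAngleSeries, states_1based: Sequence[int]
) -> float:
    """Joint log-probability of a given state path with the observations."""
    s = np.asarray(states_1based, dtype=int) - 1
    with np.errstate(divide="ignore"):
        logA = np.nan_to_num(np.log(params.transition), neginf=_LOG_EPS)
        log_init = np.nan_to_num(np.log(params.initial), neginf=_LOG_EPS)
    logB = _emission_logprob(params, series)
    lp = log_init[s[0]] + logB[0, s[0]]
    for t in range(1, s.size):
        lp += logA[s[t - 1], s[t]] + logB[t, s[t]]
    return float(lp)


# ---------------------------------------------------------------------------
# Fitting


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _unpack(theta: np.ndarray, n: int) -> HMMParameters:
    k = 0
    states = []
    for _ in range(n):
        lm, ls, lz, lk = theta[k : k + 4]
        k += 4
        states.append(
            StateModel(
                step_zero_mass=float(special.expit(lz)),
                step_mean=float(np.exp(lm)),
                step_sd=float(np.exp(ls)),
                angle_mean=0.0,
                angle_kappa=float(np.exp(lk)),
            )
        )
    rowz = np.zeros((n, n))
    for i in range(n):
        off = theta[k : k + n - 1]
        k += n - 1
        rowz[i, np.arange(n) != i] = off  # diagonal logit fixed at 0
    A = _softmax_rows(rowz)
    initz = np.zeros(n)
    initz[1:] = theta[k : k + n - 1]
    pi0 = _softmax_rows(initz[None, :])[0]
    return HMMParameters(states=tuple(states), transition=A, initial=pi0)


def _canonical_order(params: HMMParameters) -> HMMParameters:
    order = np.argsort([s.step_mean for s in params.states], kind="stable")
    states = tuple(params.states[i] for i in order)
    A = params.transition[np.ix_(order, order)]
    pi0 = params.initial[order]
    return replace(params, states=states, transition=A, initial=pi0)


def _batched_negloglik(theta, n, step_batches, angle_batches):
    """Negative log-likelihood over series grouped by common length.

    Each batch is (steps [S, T], angles [S, T-1]); the forward recursion
    runs vectorised over the S series of a batch.
    """
    p = _unpack(theta, n)
    with np.errstate(divide="ignore"):
        logA = np.nan_to_num(np.log(p.transition), neginf=_LOG_EPS)
        log_init = np.nan_to_num(np.log(p.initial), neginf=_LOG_EPS)
    A = np.exp(logA)
    total = 0.0
    for steps, angles in zip(step_batches, angle_batches):
        S, T = steps.shape
        logB = np.zeros((S, T, n))
        zero = steps == 0.0
        posmask = ~zero
        for j, st in enumerate(p.states):
            col = np.where(
                zero,
                math.log(st.step_zero_mass) if st.step_zero_mass > 0 else _LOG_EPS,
                0.0,
            )
            if posmask.any():
                vals = _gamma_logpdf(steps[posmask], st.step_mean, st.step_sd)
                base = math.log1p(-st.step_zero_mass) if st.step_zero_mass < 1 else _LOG_EPS
                col = col.copy()
                col[posmask] = base + vals
            logB[:, :, j] = col
            ok = ~np.isnan(angles)
            if ok.any():
                la = np.zeros_like(angles)
                la[ok] = _vonmises_logpdf(angles[ok], st.angle_mean, st.angle_kappa)
                logB[:, 1:, j] += la
        alpha = log_init[None, :] + logB[:, 0, :]
        for t in range(1, T):
            m = alpha.max(axis=1, keepdims=True)
            alpha = m + np.log(np.exp(alpha - m) @ A) + logB[:, t, :]
        m = alpha.max(axis=1)
        total += float((m + np.log(np.exp(alpha - m[:, None]).sum(axis=1))).sum())
    if not np.isfinite(total):
        return 1e12
    return -total


def _initial_theta(series_list, n, rng, jitter: bool) -> np.ndarray:
    steps = np.concatenate([s.steps for s in series_list])
    pos = steps[steps > 0]
    f0 = float((steps == 0).mean())
    qs = np.quantile(pos, np.linspace(0.12, 0.88, n))
    qs = np.maximum(qs, pos.min() * 0.5 + 1e-9)
    means = qs.copy()
    sds = np.maximum(means, 1e-6)
    zm = np.clip(
        np.geomspace(max(2.5 * f0 + 0.02, 0.05), max(f0 / 5 + 1e-3, 5e-3), n), 1e-4, 0.95
    )
    kappas = np.geomspace(0.05, 2.0, n)
    theta = []
    for j in range(n):
        lm = math.log(means[j])
        ls = math.log(sds[j])
        lz = float(special.logit(zm[j]))
        lk = math.log(kappas[j])
        if jitter:
            lm += rng.normal(0, 0.4)
            ls += rng.normal(0, 0.4)
            lz += rng.normal(0, 0.6)
            lk += rng.normal(0, 0.6)
        theta += [lm, ls, lz, lk]
    # transitions: sticky diagonal (logit ~ log(0.8/0.1) off-diag ~ -2)
    for _ in range(n * (n - 1)):
        theta.append(-2.0 + (rng.normal(0, 0.3) if jitter else 0.0))
    for _ in range(n - 1):
        theta.append(0.0 + (rng.normal(0, 0.3) if jitter else 0.0))
    return np.array(theta)


def fit_hmm(
    series_list: Sequence[StepAngleSeries],
    n_states: int = 3,
    n_starts: int = 25,
    seed: int = 0,
) -> HMMParameters:
    """Maximum-likelihood HMM fit with multi-start initialisation.

    Optimises the forward log-likelihood over an unconstrained
    reparameterisation (log step mean/SD, logit zero-mass, log kappa,
    multinomial-logit transition rows and initial distribution) from
    ``n_starts`` perturbed initialisations; returns the best solution
    with states ordered by ascending mean step length.  Deterministic
    given ``seed`` and data.
    """
    steps_all = np.concatenate([s.steps for s in series_list])
    n_pos = int((steps_all > 0).sum())
    if n_pos == 0:
        raise ValueError("all steps are zero: no movement to model")
    if n_pos < 10 * n_states:
        raise ValueError(
            f"need at least {10 * n_states} positive steps, got {n_pos}"
        )
    # batch series by common length for a vectorised forward pass; sort
    # within batches so the fit is invariant to the order tracks arrive in
    by_T: dict[int, list[StepAngleSeries]] = {}
    for s in series_list:
        by_T.setdefault(s.T, []).append(s)
    step_batches, angle_batches = [], []
    for T, group in sorted(by_T.items()):
        group = sorted(group, key=lambda g: g.track_id)
        step_batches.append(np.stack([g.steps for g in group]))
        angle_batches.append(np.stack([g.angles for g in group]))

    pos = steps_all[steps_all > 0]
    lo_m, hi_m = math.log(pos.min()) - 5.0, math.log(pos.max()) + 3.0
    bounds = []
    for _ in range(n_states):
        bounds += [(lo_m, hi_m), (lo_m, hi_m), (-15.0, 15.0), (-10.0, 6.0)]
    bounds += [(-15.0, 15.0)] * (n_states * (n_states - 1) + n_states - 1)

    rng = np.random.default_rng(seed)
    best = None
    tried = []
    for start in range(n_starts):
        theta0 = _initial_theta(series_list, n_states, rng, jitter=start > 0)
        theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _batched_negloglik,
            theta0,
            args=(n_states, step_batches, angle_batches),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300},
        )
        tried.append(res)
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            "no optimisation start converged to a finite likelihood; "
            f"messages: {[r.message for r in tried]}"
        )
    params = _canonical_order(_unpack(best.x, n_states))
    return replace(params, loglik=-float(best.fun))


def simulate_series(
    params: HMMParameters,
    T: int,
    rng: np.random.Generator | int | None = None,
    track_id: str = "sim",
) -> tuple[StepAngleSeries, np.ndarray]:
    """Draw one observation series and its generating state path (1-based)."""
    rng = np.random.default_rng(rng)
    n = params.n_states
    states = np.empty(T, dtype=int)
    states[0] = rng.choice(n, p=params.initial)
    for t in range(1, T):
        states[t] = rng.choice(n, p=params.transition[states[t - 1]])
    steps = np.empty(T)
    for t in range(T):
        st = params.states[states[t]]
        if rng.random() < st.step_zero_mass:
            steps[t] = 0.0
        else:
            shape = (st.step_mean / st.step_sd) ** 2
            scale = st.step_sd**2 / st.step_mean
            steps[t] = rng.gamma(shape, scale)
    angles = np.empty(max(T - 1, 0))
    for t in range(1, T):
        st = params.states[states[t]]
        angles[t - 1] = wrap_angle(rng.vonmises(st.angle_mean, max(st.angle_kappa, 1e-12)))
    zero = steps == 0.0
    if T > 1:
        angles[zero[:-1] | zero[1:]] = np.nan
    return StepAngleSeries(steps=steps, angles=angles, track_id=track_id), states + 1


# ---------------------------------------------------------------------------
# State-conditional deviation (metres per minute)


def state_conditional_deviation(
    original_track: Track,
    grid_interval_s: float,
    decoded: DecodedTrack,
) -> tuple[dict[int, BoxSummary], np.ndarray]:
    """Per-grid-cell deviation rates grouped by decoded movement state.

    For grid cell i the deviation rate is (original sub-path length within
    the cell minus the straight-line step length) divided by the grid
    interval in minutes — how many metres per minute of real travel the
    re-discretisation discards in that cell.  Returns a BoxSummary per
    state label plus the raw per-cell rates (aligned with the decoded
    states).
    """
    if original_track.frame != LOCAL_METRIC:
        raise ValueError("original track must be local-metric")
    T = decoded.series.T
    grid = original_track.t[0] + grid_interval_s * np.arange(T + 1)
    if grid[-1] > original_track.t[-1] + 1e-6:
        raise ValueError("decoded grid extends beyond the original track")
    # cumulative arc length along the original polyline is piecewise
    # linear in time (constant speed within each leg)
    seg = np.hypot(np.diff(original_track.x), np.diff(original_track.y))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = np.interp(grid, original_track.t, cum)
    sub_lengths = np.diff(L)
    if sub_lengths.size != T:
        raise ValueError("grid cells do not match decoded series length")
    rates = (sub_lengths - decoded.series.steps) / (grid_interval_s / 60.0)
    summaries = {
        int(lab): box_summary(rates[decoded.states == lab])
        for lab in np.unique(decoded.states)
    }
    return summaries, rates
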