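"""Movement HMM: emissions, forward likelihood, Viterbi, fitting."""

import itertools
import math

import numpy as np
import pytest
from scipy import special, stats as sps

from trackthin.hmm import (
    DecodedTrack,
    HMMParameters,
    StateModel,
    StepAngleSeries,
    _emission_logprob,
    fit_hmm,
    hmm_loglik,
    path_logprob,
    simulate_series,
    state_conditional_deviation,
    steps_and_angles,
    viterbi,
    viterbi_path_logprob,
    wrap_angle,
)
from trackthin.resample import resample_time_regular
from trackthin.trackio import LOCAL_METRIC, Track

WELL_SEPARATED = HMMParameters(
    states=(
        StateModel(step_zero_mass=0.4, step_mean=1.0, step_sd=0.8, angle_kappa=1e-6),
        StateModel(step_zero_mass=0.02, step_mean=20.0, step_sd=12.0, angle_kappa=0.3),
        StateModel(step_zero_mass=0.0, step_mean=120.0, step_sd=40.0, angle_kappa=2.0),
    ),
    transition=np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]]),
    initial=np.array([0.4, 0.35, 0.25]),
)


def random_params(rng: np.random.Generator, n: int = 3) -> HMMParameters:
    means = np.sort(rng.uniform(0.5, 150.0, n))
    states = tuple(
        StateModel(
            step_zero_mass=float(rng.uniform(0, 0.9)),
            step_mean=float(m),
            step_sd=float(m * rng.uniform(0.3, 1.2)),
            angle_kappa=float(rng.uniform(0, 3)),
        )
        for m in means
    )
    A = rng.dirichlet(np.ones(n) * 2, size=n)
    pi0 = rng.dirichlet(np.ones(n))
    return HMMParameters(states=states, transition=A, initial=pi0)


def random_series(rng: np.random.Generator, T: int) -> StepAngleSeries:
    steps = rng.gamma(1.5, 20.0, T)
    steps[rng.random(T) < 0.25] = 0.0
    angles = wrap_angle(rng.uniform(-math.pi, math.pi, max(T - 1, 0)))
    zero = steps == 0.0
    if T > 1:
        angles[zero[:-1] | zero[1:]] = np.nan
    return StepAngleSeries(steps=steps, angles=angles, track_id="r")


def enumeration_loglik(params: HMMParameters, series: StepAngleSeries) -> float:
    """Brute force: sum the joint probability over all n^T state paths."""
    n, T = params.n_states, series.T
    logB = _emission_logprob(params, series)
    total = -np.inf
    for path in itertools.product(range(n), repeat=T):
        lp = math.log(params.initial[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += math.log(params.transition[path[t - 1], path[t]]) + logB[t, path[t]]
        total = np.logaddexp(total, lp)
    return float(total)


def enumeration_best_path(params: HMMParameters, series: StepAngleSeries):
    n, T = params.n_states, series.T
    logB = _emission_logprob(params, series)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(n), repeat=T):
        lp = math.log(params.initial[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += math.log(params.transition[path[t - 1], path[t]]) + logB[t, path[t]]
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, np.array(best_path) + 1


class TestStepsAndAngles:
    def _track(self, xy, dt=300.0):
        xy = np.asarray(xy, dtype=float)
        return Track("t", "s", dt * np.arange(len(xy)), xy[:, 0], xy[:, 1], LOCAL_METRIC)

    def test_collinear_eastbound_zero_angles(self):
        s = steps_and_angles(self._track([(0, 0), (10, 0), (20, 0), (30, 0)]))
        np.testing.assert_allclose(s.steps, 10.0)
        np.testing.assert_allclose(s.angles, 0.0)

    def test_ccw_square_quarter_turns(self):
        # east, north, west, south: three left turns of +pi/2
        s = steps_and_angles(self._track([(0, 0), (10, 0), (10, 10), (0, 10), (0, 0)]))
        np.testing.assert_allclose(s.angles, math.pi / 2)

    def test_cw_square_negative_quarter_turns(self):
        s = steps_and_angles(self._track([(0, 0), (10, 0), (10, -10), (0, -10), (0, 0)]))
        np.testing.assert_allclose(s.angles, -math.pi / 2)

    def test_u_turn_maps_to_plus_pi(self):
        s = steps_and_angles(self._track([(0, 0), (10, 0), (0, 0)]))
        assert s.angles[0] == pytest.approx(math.pi)

    def test_stationary_track_all_missing_angles(self):
        s = steps_and_angles(self._track([(1, 1)] * 5))
        np.testing.assert_allclose(s.steps, 0.0)
        assert np.isnan(s.angles).all()

    def test_irregular_grid_rejected(self):
        tr = Track("t", "s", [0, 300, 650], [0, 1, 2], [0, 0, 0], LOCAL_METRIC)
        with pytest.raises(ValueError, match="irregular"):
            steps_and_angles(tr)


class TestForwardLikelihood:
    def test_matches_enumeration(self, rng):
        for _ in range(10):
            params = random_params(rng)
            series = random_series(rng, T=6)
            ours = hmm_loglik(params, [series])
            brute = enumeration_loglik(params, series)
            assert ours == pytest.approx(brute, abs=1e-8)

    def test_additive_over_series(self, rng):
        params = random_params(rng)
        s = random_series(rng, T=50)
        assert hmm_loglik(params, [s, s]) == pytest.approx(2 * hmm_loglik(params, [s]), rel=1e-12)

    def test_single_state_reduces_to_gamma_loglik(self, rng):
        steps = rng.gamma(2.0, 10.0, 40)
        series = StepAngleSeries(steps=steps, angles=np.full(39, np.nan))
        st = StateModel(step_zero_mass=0.0, step_mean=20.0, step_sd=14.0)
        params = HMMParameters(states=(st,), transition=np.array([[1.0]]), initial=np.array([1.0]))
        shape = (20.0 / 14.0) ** 2
        ref = sps.gamma.logpdf(steps, shape, scale=14.0**2 / 20.0).sum()
        assert hmm_loglik(params, [series]) == pytest.approx(ref, rel=1e-10)

    def test_no_underflow_on_long_series(self, rng):
        series = random_series(rng, T=2000)
        ll = hmm_loglik(WELL_SEPARATED, [series])
        assert np.isfinite(ll)


class TestViterbi:
    def test_matches_enumeration(self, rng):
        for _ in range(10):
            params = random_params(rng)
            series = random_series(rng, T=6)
            dec = viterbi(params, series)
            best_lp, best_path = enumeration_best_path(params, series)
            assert path_logprob(params, series, dec.states) == pytest.approx(best_lp, abs=1e-8)

    def test_path_probability_bounded_by_total(self, rng):
        params = random_params(rng)
        series = random_series(rng, T=40)
        assert viterbi_path_logprob(params, series) <= hmm_loglik(params, [series]) + 1e-12

    def test_near_deterministic_recovery(self, rng):
        series, states = simulate_series(WELL_SEPARATED, 200, rng)
        dec = viterbi(WELL_SEPARATED, series)
        assert (dec.states == states).mean() > 0.9

    def test_label_permutation_equivariance(self, rng):
        params = random_params(rng)
        series = random_series(rng, T=30)
        perm = np.array([2, 0, 1])
        inv = np.argsort(perm)
        permuted = HMMParameters(
            states=tuple(params.states[i] for i in perm),
            transition=params.transition[np.ix_(perm, perm)],
            initial=params.initial[perm],
        )
        d0 = viterbi(params, series).states
        d1 = viterbi(permuted, series).states
        assert np.array_equal(inv[d0 - 1] + 1, d1)


class TestFitHmm:
    def test_single_state_matches_direct_gamma_mle(self, rng):
        steps = rng.gamma(2.5, 8.0, 400)
        series = StepAngleSeries(steps=steps, angles=np.full(399, np.nan))
        params = fit_hmm([series], n_states=1, n_starts=3, seed=1)
        st = params.states[0]

        def negll(x):
            m, s = np.exp(x)
            a, scale = (m / s) ** 2, s**2 / m
            return -sps.gamma.logpdf(steps, a, scale=scale).sum()

        from scipy.optimize import minimize

        direct = minimize(negll, np.log([steps.mean(), steps.std()]), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12})
        m_ref, s_ref = np.exp(direct.x)
        assert st.step_mean == pytest.approx(m_ref, rel=1e-3)
        assert st.step_sd == pytest.approx(s_ref, rel=1e-3)

    def test_recovery_well_separated(self, rng):
        series = [simulate_series(WELL_SEPARATED, 24, rng, f"t{i}")[0] for i in range(47)]
        fitted = fit_hmm(series, n_states=3, n_starts=4, seed=7)
        for f, true in zip(fitted.states, WELL_SEPARATED.states):
            assert abs(f.step_mean - true.step_mean) / true.step_mean < 0.15
        # fitted loglik at least as high as at the generating parameters
        assert fitted.loglik >= hmm_loglik(WELL_SEPARATED, series) - 1e-6

    def test_states_canonically_ordered(self, rng):
        series = [simulate_series(WELL_SEPARATED, 24, rng, f"t{i}")[0] for i in range(20)]
        params = fit_hmm(series, n_states=3, n_starts=2, seed=3)
        means = [s.step_mean for s in params.states]
        assert means == sorted(means)
        assert np.allclose(params.transition.sum(axis=1), 1.0, atol=1e-10)
        assert params.initial.sum() == pytest.approx(1.0, abs=1e-10)

    def test_deterministic_given_seed(self, rng):
        series = [simulate_series(WELL_SEPARATED, 24, rng, f"t{i}")[0] for i in range(10)]
        p1 = fit_hmm(series, n_states=3, n_starts=2, seed=5)
        p2 = fit_hmm(series, n_states=3, n_starts=2, seed=5)
        for a, b in zip(p1.states, p2.states):
            assert a == b
        np.testing.assert_array_equal(p1.transition, p2.transition)

    def test_invariant_to_track_order(self, rng):
        series = [simulate_series(WELL_SEPARATED, 24, rng, f"t{i}")[0] for i in range(10)]
        p1 = fit_hmm(series, n_states=3, n_starts=2, seed=5)
        p2 = fit_hmm(series[::-1], n_states=3, n_starts=2, seed=5)
        np.testing.assert_allclose(
            [s.step_mean for s in p1.states], [s.step_mean for s in p2.states], rtol=1e-6
        )

    def test_all_zero_steps_rejected(self):
        series = StepAngleSeries(steps=np.zeros(50), angles=np.full(49, np.nan))
        with pytest.raises(ValueError, match="zero"):
            fit_hmm([series], n_states=3)


class TestStateConditionalDeviation:
    def test_resting_and_straight_cells_zero_rate(self):
        # 0-600 s: stationary; 600-1200 s: straight at constant speed
        t = np.arange(0, 1201, 30.0)
        x = np.where(t <= 600, 0.0, (t - 600) * 0.5)
        y = np.zeros_like(t)
        tr = Track("t", "s", t, x, y, LOCAL_METRIC)
        res = resample_time_regular(tr, 300.0, include_terminal=False)
        series = steps_and_angles(res)
        dec = DecodedTrack(series=series, states=np.array([1, 1, 3, 3]))
        summaries, rates = state_conditional_deviation(tr, 300.0, dec)
        np.testing.assert_allclose(rates, 0.0, atol=1e-12)
        assert summaries[1].median == 0.0 and summaries[3].median == 0.0

    def test_rate_units_metres_per_minute(self):
        # one 5-min cell walking a 3-4-5 dogleg: path 70 m, chord 50 m
        tr = Track("t", "s", [0.0, 150.0, 300.0], [0.0, 30.0, 30.0], [0.0, 0.0, 40.0],
                   LOCAL_METRIC)
        res = resample_time_regular(tr, 300.0, include_terminal=False)
        # single-step series has no angle; build the 1-cell decoded track
        series = StepAngleSeries(steps=np.hypot(np.diff(res.x), np.diff(res.y)),
                                 angles=np.empty(0))
        dec = DecodedTrack(series=series, states=np.array([2]))
        _, rates = state_conditional_deviation(tr, 300.0, dec)
        assert rates[0] == pytest.approx((70.0 - 50.0) / 5.0)

    def test_state_ordering_on_synthetic_cohort(self, rng):
        """Faster, more meandering states shed more metres per minute."""
        from trackthin.synth import SimulationConfig, simulate_cohort

        truth = simulate_cohort(SimulationConfig(n_tracks=12, seed=21))
        all_rates, all_states = [], []
        series = []
        tracks = []
        for tr in truth.tracks:
            res = resample_time_regular(tr, 300.0, include_terminal=False)
            series.append(steps_and_angles(res))
            tracks.append(tr)
        params = fit_hmm(series, n_states=3, n_starts=3, seed=2)
        for tr, s in zip(tracks, series):
            dec = viterbi(params, s)
            _, rates = state_conditional_deviation(tr, 300.0, dec)
            all_rates.append(rates)
            all_states.append(dec.states)
        rates = np.concatenate(all_rates)
        states = np.concatenate(all_states)
        med = {k: np.median(rates[states == k]) for k in (1, 2, 3)}
        assert med[1] < med[2] < med[3]

    def test_length_mismatch_rejected(self, triangle_track):
        series = StepAngleSeries(steps=np.ones(5), angles=np.zeros(4))
        dec = DecodedTrack(series=series, states=np.ones(5, dtype=int))
        with pytest.raises(ValueError):
            state_conditional_deviation(triangle_track, 300.0, dec)
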