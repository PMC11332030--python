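import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiomotor import (
    FAST_BAND,
    SLOW_BAND,
    EnvelopeSignal,
    InvalidInputError,
    PhaseSeries,
    permutation_baseline,
    plv,
    score_condition,
    windowed_plv,
)
from audiomotor.sync_metrics import PLVEstimate, window_starts

from conftest import noise_envelope


def brute_force_plv(theta1, theta2):
    """Independent oracle: direct complex summation at full precision."""
    total = 0.0 + 0.0j
    for a, b in zip(theta1, theta2):
        total += complex(np.cos(a - b), np.sin(a - b))
    return abs(total) / len(theta1)


class TestPlv:
    def test_identical_phases_give_one(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(-np.pi, np.pi, 500)
        assert plv(th, th) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_invariance(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(-np.pi, np.pi, 500)
        assert plv(th + np.pi / 3, th) == pytest.approx(1.0, abs=1e-12)

    def test_three_equally_spaced_differences_cancel(self):
        d = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
        assert plv(d, np.zeros(3)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for n in (10, 1000, 100_000):
            a = rng.uniform(-np.pi, np.pi, n)
            b = rng.uniform(-np.pi, np.pi, n)
            assert plv(a, b) == pytest.approx(brute_force_plv(a, b), abs=1e-12)

    def test_rayleigh_mean_for_uniform_phase_differences(self):
        # E[PLV] for T i.i.d. uniform phases ~ sqrt(pi)/(2 sqrt(T))
        rng = np.random.default_rng(3)
        T, reps = 1000, 3000
        vals = [plv(rng.uniform(0, 2 * np.pi, T), np.zeros(T)) for _ in range(reps)]
        expected = np.sqrt(np.pi) / (2 * np.sqrt(T))
        assert np.mean(vals) == pytest.approx(expected, rel=0.05)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            plv(np.zeros(5), np.zeros(4))

    @given(st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_plv_bounded_and_offset_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, 64)
        b = rng.uniform(-np.pi, np.pi, 64)
        v = plv(a, b)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert plv(a + 1.234, b) == pytest.approx(v, abs=1e-12)


class TestWindowedPlv:
    def test_fast_preset_window_count(self):
        # 50 s series, 5 s windows, 3 s hop -> 16 windows starting 0,3,...,45
        starts = window_starts(5000, 100.0, FAST_BAND)
        assert len(starts) == 16
        np.testing.assert_array_equal(starts[:3], [0, 300, 600])
        assert starts[-1] == 4500

    def test_slow_preset_single_window(self):
        th = PhaseSeries(np.zeros(1100), 100.0, SLOW_BAND)
        raw, wins = windowed_plv(th, th, SLOW_BAND)
        assert len(wins) == 1
        assert raw == 1.0

    def test_identical_series_all_windows_one(self):
        rng = np.random.default_rng(4)
        th = PhaseSeries(rng.uniform(-np.pi, np.pi, 2000), 100.0, FAST_BAND)
        raw, wins = windowed_plv(th, th, FAST_BAND)
        assert raw == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(wins - 1.0) < 1e-12)

    def test_raw_is_mean_of_windows(self):
        rng = np.random.default_rng(5)
        a = PhaseSeries(rng.uniform(-np.pi, np.pi, 3000), 100.0, FAST_BAND)
        b = PhaseSeries(rng.uniform(-np.pi, np.pi, 3000), 100.0, FAST_BAND)
        raw, wins = windowed_plv(a, b, FAST_BAND)
        assert raw == pytest.approx(wins.mean(), abs=1e-12)
        assert np.all((wins >= 0) & (wins <= 1))

    def test_shorter_than_one_window_rejected(self):
        th = PhaseSeries(np.zeros(400), 100.0, FAST_BAND)
        with pytest.raises(InvalidInputError):
            windowed_plv(th, th, FAST_BAND)


class TestPermutationBaseline:
    def test_single_segment_degenerates_to_identity(self):
        rng = np.random.default_rng(6)
        env1 = EnvelopeSignal(np.abs(rng.standard_normal(1500)), 100.0)
        env2 = EnvelopeSignal(np.abs(rng.standard_normal(1500)), 100.0)
        with pytest.warns(UserWarning):
            est = permutation_baseline(env1, env2, SLOW_BAND, n_permutations=5, seed=0)
        assert est.baseline_plv == est.raw_plv
        assert est.normalized_plv == 0.0

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(7)
        env1 = EnvelopeSignal(np.abs(rng.standard_normal(4000)), 100.0)
        env2 = EnvelopeSignal(np.abs(rng.standard_normal(4000)), 100.0)
        a = permutation_baseline(env1, env2, SLOW_BAND, n_permutations=5, seed=11)
        b = permutation_baseline(env1, env2, SLOW_BAND, n_permutations=5, seed=11)
        assert a.baseline_plv == b.baseline_plv

    def test_normalized_never_exceeds_raw(self):
        rng = np.random.default_rng(8)
        env1 = noise_envelope(rng, 40)
        env2 = noise_envelope(rng, 40)
        est = permutation_baseline(env1, env2, SLOW_BAND, n_permutations=10, seed=1)
        assert est.normalized_plv <= est.raw_plv
        assert 0.0 <= est.raw_plv <= 1.0
        assert 0.0 <= est.baseline_plv <= 1.0

    def test_null_centering_small(self):
        # reduced-size version of the null calibration (full run in acceptance)
        vals = []
        for s in range(25):
            rng = np.random.default_rng(s)
            est = permutation_baseline(
                noise_envelope(rng), noise_envelope(rng), SLOW_BAND,
                n_permutations=20, seed=s + 500,
            )
            vals.append(est.normalized_plv)
        assert abs(np.mean(vals)) < 0.04


class TestScoreCondition:
    def _estimate(self, norm):
        return PLVEstimate(norm + 0.1, 0.1, norm, np.array([norm]), SLOW_BAND, 1, 1)

    def test_mean_of_trials(self):
        trials = [self._estimate(0.30), self._estimate(0.40)]
        score = score_condition(trials, "P000", "tap", "tone", "slow")
        assert score.plv == pytest.approx(0.35)
        assert score.n_trials == 2

    def test_single_trial_identity(self):
        score = score_condition([self._estimate(0.2)], "P0", "tap", "tone", "slow")
        assert score.plv == pytest.approx(0.2)

    def test_zeros(self):
        score = score_condition([self._estimate(0.0)] * 3, "P0", "tap", "tone", "slow")
        assert score.plv == 0.0

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            score_condition([], "P0", "tap", "tone", "slow")
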