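"""Time-domain EMG feature bank: closed-form examples, brute-force oracles,
statistical consistency, and scaling behavior."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from statsmodels.regression.linear_model import yule_walker

import gaitdx.features_emg as fe
from gaitdx.errors import ConfigurationError, SegmentTooShortError, UndefinedFeatureError

SEGMENTS = st.builds(
    lambda seed, n: np.random.default_rng(seed).standard_normal(n) + 0.1,
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(30, 400),
)


class TestClosedFormExamples:
    def test_lmav_of_unit_alternation_is_zero(self):
        assert fe.lmav([-1, 1, -1, 1]) == pytest.approx(0.0)

    def test_lmav_of_constant_e_is_one(self):
        assert fe.lmav(np.full(10, np.e)) == pytest.approx(1.0)

    def test_lmav_rejects_all_zero(self):
        with pytest.raises(UndefinedFeatureError):
            fe.lmav(np.zeros(5))

    def test_nsv_fixed_points(self):
        assert fe.nsv(np.ones(7)) == pytest.approx(1.0)
        assert fe.nsv(np.zeros(7)) == pytest.approx(0.0)

    def test_waveform_length_of_unit_steps(self):
        assert fe.waveform_length([0, 1, 0, 1]) == pytest.approx(3.0)
        assert fe.waveform_length(np.full(9, 2.2)) == pytest.approx(0.0)

    def test_threshold_counts_on_constructed_patterns(self):
        wamp, _, _ = fe.threshold_counts([0, 1, 0, 1], theta_wamp=0.5)
        assert wamp == 3
        _, zc, _ = fe.threshold_counts([1, -1, 1, -1], theta_zc=0.0)
        assert zc == 3
        _, _, ssc = fe.threshold_counts([0, 1, 0, 1, 0], theta_ssc=0.0)
        assert ssc == 3

    def test_negative_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            fe.threshold_counts([0, 1, 0], theta_wamp=-1.0)

    def test_hjorth_degenerate_conventions(self):
        assert fe.hjorth_params(np.arange(5.0)) == (0.0, 0.0)  # linear ramp
        assert fe.hjorth_params(np.full(5, 3.0)) == (0.0, 0.0)

    def test_moments_on_alternating_segment(self):
        m0, m2, _, _ = fe.td_spectral_moments([1, -1, 1, -1])
        assert m0 == pytest.approx(4.0)
        assert m2 == pytest.approx(12.0)
        assert fe.td_spectral_moments(np.zeros(8)) == (0.0, 0.0, 0.0, 0.0)

    def test_amplitude_changes_examples(self):
        ac1, _ = fe.amplitude_changes([0, 1, 0, 1])
        assert ac1 == pytest.approx(1.0)
        assert fe.amplitude_changes(np.full(6, 4.2)) == (0.0, 0.0)


class TestBruteForceOracles:
    """Each feature equals an independently coded two-step formula."""

    def test_scalar_features_match_oracles(self, rng):
        x = rng.standard_normal(512) + 0.2
        assert fe.lmav(x) == pytest.approx(np.log(np.mean(np.abs(x))))
        assert fe.nsv(x, 3) == pytest.approx(np.mean(np.abs(x) ** 3) ** (1 / 3))
        assert fe.waveform_length(x) == pytest.approx(
            sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))
        )
        ac1, ac2 = fe.amplitude_changes(x)
        assert ac1 == pytest.approx(np.mean(np.abs(np.diff(x))))
        assert ac2 == pytest.approx(np.mean(np.abs(np.diff(np.diff(x)))))
        m0, m2, m4, m6 = fe.td_spectral_moments(x)
        assert m0 == pytest.approx(np.sum(x**2))
        assert m6 == pytest.approx(np.sum(np.diff(x, n=3) ** 2))

    def test_hjorth_matches_variance_ratio_oracle(self, rng):
        x = rng.standard_normal(400)
        mob, com = fe.hjorth_params(x)
        mob_oracle = np.sqrt(np.var(np.diff(x)) / np.var(x))
        assert mob == pytest.approx(mob_oracle)
        d = np.diff(x)
        com_oracle = np.sqrt(np.var(np.diff(d)) / np.var(d)) / mob_oracle
        assert com == pytest.approx(com_oracle)

    def test_skewness_matches_population_estimator(self, rng):
        x = rng.gamma(2.0, size=600)
        m = x.mean()
        oracle = np.mean((x - m) ** 3) / np.mean((x - m) ** 2) ** 1.5
        assert fe.skewness(x) == pytest.approx(oracle)

    def test_threshold_counts_match_loop_oracle(self, rng):
        x = rng.standard_normal(300)
        tw, tz, ts = 0.3, 0.1, 0.2
        wamp, zc, ssc = fe.threshold_counts(x, tw, tz, ts)
        assert wamp == sum(abs(x[i + 1] - x[i]) >= tw for i in range(len(x) - 1))
        assert zc == sum(
            x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= tz for i in range(len(x) - 1)
        )
        assert ssc == sum(
            (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
            and max(abs(x[i] - x[i - 1]), abs(x[i] - x[i + 1])) >= ts
            for i in range(1, len(x) - 1)
        )

    def test_ar_matches_yule_walker_reference(self, rng):
        x = rng.standard_normal(2000)
        mine = fe.ar_coefficients(x, order=4)
        ref, _ = yule_walker(x, order=4, method="mle", demean=False)
        np.testing.assert_allclose(mine, ref, rtol=1e-8)


class TestArConsistency:
    def test_recovers_ar1_coefficient(self, rng):
        n = 5000
        x = np.zeros(n)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.8 * x[t - 1] + eps[t]
        ar = fe.ar_coefficients(x, order=4)
        assert ar[0] == pytest.approx(0.8, abs=0.05)

    def test_white_noise_has_negligible_ar_structure(self, rng):
        ar = fe.ar_coefficients(rng.standard_normal(5000), order=4)
        assert np.all(np.abs(ar) < 0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedFeatureError):
            fe.ar_coefficients(np.ones(100))


class TestFeatureVector:
    def test_vector_has_19_named_slots_in_canonical_order(self, rng):
        x = rng.standard_normal(500) + 0.1
        vec = fe.emg_feature_vector(x, "GL")
        assert len(vec) == 19
        assert vec.names == [f"GL__{n}" for n in fe.EMG_FEATURE_NAMES]

    def test_vector_is_deterministic(self, rng):
        x = rng.standard_normal(400) + 0.1
        a = fe.emg_feature_vector(x, "GL")
        b = fe.emg_feature_vector(x, "GL")
        np.testing.assert_array_equal(a.values, b.values)

    def test_each_slot_equals_its_standalone_operation(self, rng):
        x = rng.standard_normal(600) + 0.1
        cfg = fe.EmgFeatureConfig()
        vec = fe.emg_feature_vector(x, "TA", cfg).as_dict()
        assert vec["TA__LMAV"] == pytest.approx(fe.lmav(x))
        assert vec["TA__NSV"] == pytest.approx(fe.nsv(x, cfg.nsv_order))
        assert vec["TA__WL"] == pytest.approx(fe.waveform_length(x))
        wamp, zc, ssc = fe.threshold_counts(x, cfg.theta_wamp, cfg.theta_zc, cfg.theta_ssc)
        assert (vec["TA__WAMP"], vec["TA__ZC"], vec["TA__SSC"]) == (wamp, zc, ssc)
        mob, com = fe.hjorth_params(x)
        assert vec["TA__MOB"] == pytest.approx(mob)
        assert vec["TA__COM"] == pytest.approx(com)
        np.testing.assert_allclose(
            [vec["TA__AR1"], vec["TA__AR2"], vec["TA__AR3"], vec["TA__AR4"]],
            fe.ar_coefficients(x, cfg.ar_order),
        )
        assert vec["TA__SKW"] == pytest.approx(fe.skewness(x))
        m0, m2, m4, m6 = fe.td_spectral_moments(x)
        assert vec["TA__m6"] == pytest.approx(m6)
        ac1, ac2 = fe.amplitude_changes(x)
        assert vec["TA__AC2"] == pytest.approx(ac2)

    def test_error_carries_channel_context(self):
        with pytest.raises(UndefinedFeatureError, match="VL"):
            fe.emg_feature_vector(np.zeros(500), "VL")

    def test_short_segment_rejected(self, rng):
        with pytest.raises(SegmentTooShortError):
            fe.emg_feature_vector(rng.standard_normal(10), "GL")


class TestScalingBehavior:
    def test_waveform_length_scales_linearly(self, rng):
        x = rng.standard_normal(300)
        assert fe.waveform_length(3.5 * x) == pytest.approx(3.5 * fe.waveform_length(x))

    def test_zero_threshold_zc_is_scale_invariant(self, rng):
        x = rng.standard_normal(300)
        _, zc1, _ = fe.threshold_counts(x, 0.0, 0.0, 0.0)
        _, zc2, _ = fe.threshold_counts(100.0 * x, 0.0, 0.0, 0.0)
        assert zc1 == zc2

    def test_hjorth_parameters_are_scale_invariant(self, rng):
        x = rng.standard_normal(300)
        np.testing.assert_allclose(fe.hjorth_params(x), fe.hjorth_params(7.0 * x))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(x=SEGMENTS)
def test_feature_vector_finite_on_random_segments(x):
    vec = fe.emg_feature_vector(x, "GL")
    assert np.all(np.isfinite(vec.values))
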