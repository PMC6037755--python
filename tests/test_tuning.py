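"""Tuning regression, latency scan, permutation test, SDF, STA."""

import numpy as np
import pytest

from attnvar.simulate import von_mises_tuning
from attnvar.stimulus import StimulusParams, generate_orientation_sequence
from attnvar.tuning import (
    estimate_tuning,
    signal_correlation,
    spike_density_function,
    sta_receptive_field,
    tuning_significance,
    visual_responsiveness,
)


def _poisson_trials(rng, tuning_vec, lag=5, n_trials=40, n_frames=200, scale=0.01):
    """Trials where E[count at bin b] = scale * tuning_vec[code at b - lag]."""
    trials = []
    for i in range(n_trials):
        seq = generate_orientation_sequence(i % 5, n_frames, StimulusParams(), "right",
                                            session_seed=77)
        lam = np.zeros(n_frames)
        lam[lag:] = tuning_vec[seq.codes[:-lag]] * scale
        trials.append((rng.poisson(lam).astype(float), seq.codes))
    return trials


class TestEstimateTuning:
    def test_noiseless_response_recovered_exactly(self):
        # deterministic linear response to the one-hot stimulus
        tuning_vec = np.linspace(1.0, 4.0, 36)
        trials = []
        for i in range(4):
            seq = generate_orientation_sequence(i, 300, StimulusParams(), "left",
                                                session_seed=3)
            counts = np.zeros(300)
            counts[5:] = tuning_vec[seq.codes[:-5]]
            trials.append((counts, seq.codes))
        tc = estimate_tuning(trials)
        assert tc.optimal_latency_ms == 50.0
        assert np.allclose(tc.responses, tuning_vec, atol=1e-8)

    def test_planted_lag_recovered(self, rng):
        vec = 8 + 38 * von_mises_tuning(np.arange(36) * 5.0, 60.0, 1.5)
        tc = estimate_tuning(_poisson_trials(rng, vec, lag=5))
        assert tc.optimal_latency_ms == 50.0

    @pytest.mark.parametrize("lag", [1, 8, 15])
    def test_other_planted_lags(self, rng, lag):
        vec = 8 + 50 * von_mises_tuning(np.arange(36) * 5.0, 120.0, 2.0)
        tc = estimate_tuning(_poisson_trials(rng, vec, lag=lag, n_trials=60))
        assert tc.optimal_latency_ms == lag * 10.0

    def test_untuned_unit_has_flat_profile(self, rng):
        vec = np.full(36, 20.0)
        tc = estimate_tuning(_poisson_trials(rng, vec, n_trials=60))
        # no lag should dominate: profile within noise of flat
        assert tc.lag_variance_profile.max() < 20 * tc.lag_variance_profile.min() + 1e-3
        assert tc.weights.std() < 0.05

    def test_too_few_observations_rejected(self):
        seq = generate_orientation_sequence(0, 20, StimulusParams(), "left")
        with pytest.raises(ValueError):
            estimate_tuning([(np.zeros(20), seq.codes)])


class TestTuningSignificance:
    def test_strongly_tuned_unit_hits_p_floor(self, rng):
        vec = 5 + 80 * von_mises_tuning(np.arange(36) * 5.0, 45.0, 2.0)
        trials = _poisson_trials(rng, vec, n_trials=60)
        tc = estimate_tuning(trials)
        p = tuning_significance(tc, trials, n_perm=200, rng=rng)
        assert p == pytest.approx(1 / 201)

    def test_constant_response_gives_zero_statistic_and_p_one(self, rng):
        # exactly equal responses -> equal weights -> one-cycle projection 0
        trials = []
        for i in range(10):
            seq = generate_orientation_sequence(i % 5, 120, StimulusParams(), "left",
                                                session_seed=8)
            trials.append((np.full(120, 3.0), seq.codes))
        tc = estimate_tuning(trials)
        assert np.allclose(tc.weights, 0.0)
        p = tuning_significance(tc, trials, n_perm=200, rng=rng)
        assert p == pytest.approx(1.0)

    def test_type_one_error_roughly_calibrated(self):
        # small-scale calibration; the full 500-unit check runs in acceptance
        rng = np.random.default_rng(17)
        rejections = 0
        n_units = 60
        for _ in range(n_units):
            vec = np.full(36, 20.0)
            trials = _poisson_trials(rng, vec, n_trials=12, n_frames=100)
            tc = estimate_tuning(trials)
            p = tuning_significance(tc, trials, n_perm=150, rng=rng)
            rejections += p < 0.05
        assert rejections <= 9  # ~ binomial(60, .05), generous upper bound

    def test_zero_permutations_rejected(self, rng):
        vec = np.full(36, 10.0)
        trials = _poisson_trials(rng, vec, n_trials=10)
        tc = estimate_tuning(trials)
        with pytest.raises(ValueError):
            tuning_significance(tc, trials, n_perm=0, rng=rng)


class TestVisualResponsiveness:
    def test_large_rate_increase_is_significant(self, rng):
        pre = rng.poisson(3, 40)
        post = pre + 20 + rng.poisson(2, 40)
        assert visual_responsiveness(pre, post) < 1e-6

    def test_hand_computed_paired_t(self):
        # diffs (4, 5, 3): mean 4, sd 1, t = 4*sqrt(3), p = 2*sf(t, df=2)
        from scipy import stats

        pre = np.array([5.0, 6.0, 7.0])
        post = np.array([9.0, 11.0, 10.0])
        expected = 2 * stats.t.sf(4.0 * np.sqrt(3.0), 2)
        assert visual_responsiveness(pre, post) == pytest.approx(expected, rel=1e-10)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(31)
        ps = [visual_responsiveness(rng.poisson(5, 30), rng.poisson(5, 30))
              for _ in range(300)]
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            visual_responsiveness([1.0], [2.0])


class TestSpikeDensityFunction:
    def _trains(self, rng, rate_hz, n, dur=1000):
        return [np.sort(rng.uniform(0, dur, rng.poisson(rate_hz * dur / 1000)))
                for _ in range(n)]

    def test_constant_rate_normalizes_to_flat_one(self):
        rng = np.random.default_rng(4)
        spikes = {(c, s): self._trains(rng, 30.0, 40)
                  for c in ("AI", "AB", "AO") for s in range(3)}
        sdf = spike_density_function(spikes, duration_ms=1000)
        post = sdf["AO"][2:]  # normalization window starts at 100 ms
        assert np.allclose(post, 1.0, atol=0.1)

    def test_doubled_condition_rate_doubles_normalized_sdf(self):
        rng = np.random.default_rng(5)
        spikes = {}
        for s in range(3):
            spikes[("AO", s)] = self._trains(rng, 20.0, 60)
            spikes[("AI", s)] = self._trains(rng, 40.0, 60)
        sdf = spike_density_function(spikes, duration_ms=1000)
        ratio = sdf["AI"][4:].mean() / sdf["AO"][4:].mean()
        assert ratio == pytest.approx(2.0, abs=0.15)


class TestStaReceptiveField:
    def test_planted_rf_peak_location(self, rng):
        grid = (8, 8)
        n_epochs = 4000
        dots = np.column_stack([
            rng.integers(0, 8, n_epochs), rng.integers(0, 8, n_epochs),
            rng.choice([-1, 1], n_epochs),
        ])
        # unit fires 60 ms after a white dot lands on (3, 5)
        drive = (dots[:, 0] == 3) & (dots[:, 1] == 5) & (dots[:, 2] == 1)
        times = (np.flatnonzero(drive) * 30.0) + 60.0
        sta, peak, diam = sta_receptive_field(times, dots, grid)
        assert peak == (3, 5)
        assert diam > 0

    def test_stimulus_blind_unit_has_flat_map(self, rng):
        dots = np.column_stack([
            rng.integers(0, 8, 3000), rng.integers(0, 8, 3000), rng.choice([-1, 1], 3000)])
        times = np.sort(rng.uniform(0, 3000 * 30.0, 500))
        sta, _, _ = sta_receptive_field(times, dots, (8, 8))
        assert np.abs(sta).max() < 0.1

    def test_no_spikes_rejected(self):
        with pytest.raises(ValueError):
            sta_receptive_field(np.array([]), np.zeros((10, 3)), (4, 4))


class TestSignalCorrelation:
    def test_identical_curves(self):
        w = np.sin(np.linspace(0, 2 * np.pi, 36))
        assert signal_correlation(w, w) == pytest.approx(1.0)

    def test_orthogonal_preferences_anticorrelated(self):
        ori = np.arange(36) * 5.0
        a = von_mises_tuning(ori, 40.0, 1.5)
        b = von_mises_tuning(ori, 130.0, 1.5)  # 90 degrees away
        assert signal_correlation(a, b) < -0.5

    def test_flat_curve_flagged_undefined(self):
        assert np.isnan(signal_correlation(np.ones(36), np.sin(np.arange(36.0))))
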