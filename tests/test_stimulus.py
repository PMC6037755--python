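"""Stimulus stream and session schedule structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.lib.stride_tricks import sliding_window_view
from scipy import integrate, stats

from attnvar.stimulus import (
    CONDITIONS,
    ScheduleConfig,
    StimulusParams,
    TrialSpec,
    build_session_schedule,
    calibrate_zcp_rate,
    embed_coherent_period,
    generate_orientation_sequence,
    sample_zcp_duration,
    trial_sequences,
    truncated_exp_mean,
)


class TestZcpSampler:
    def test_draws_within_bounds(self, stim_params, rng):
        d = sample_zcp_duration(stim_params, rng, size=5000)
        assert d.min() >= stim_params.zcp_min_s
        assert d.max() <= stim_params.zcp_max_s

    def test_sample_mean_matches_printed_mean(self, stim_params):
        rng = np.random.default_rng(7)
        d = sample_zcp_duration(stim_params, rng, size=200_000)
        assert d.mean() == pytest.approx(2.17, abs=0.02)

    def test_calibrated_rate_against_quadrature_oracle(self, stim_params):
        # independent oracle: numerically integrate the truncated density
        rate = calibrate_zcp_rate(stim_params)
        lo, hi = stim_params.zcp_min_s, stim_params.zcp_max_s
        z, _ = integrate.quad(lambda x: rate * np.exp(-rate * (x - lo)), lo, hi)
        m, _ = integrate.quad(lambda x: x * rate * np.exp(-rate * (x - lo)) / z, lo, hi)
        assert m == pytest.approx(2.17, abs=1e-9)
        assert truncated_exp_mean(rate, lo, hi) == pytest.approx(m, abs=1e-9)

    def test_ecdf_close_to_truncated_exponential_cdf(self, stim_params):
        rng = np.random.default_rng(11)
        rate = calibrate_zcp_rate(stim_params)
        d = sample_zcp_duration(stim_params, rng, size=100_000)
        lo, hi = stim_params.zcp_min_s, stim_params.zcp_max_s
        mass = 1 - np.exp(-rate * (hi - lo))
        cdf = lambda x: (1 - np.exp(-rate * (np.asarray(x) - lo))) / mass
        ks = stats.kstest(d, cdf).statistic
        assert ks < 0.01


class TestOrientationSequence:
    def test_long_sequence_has_36_distinct_orientations(self, stim_params):
        s = generate_orientation_sequence(0, 10_000, stim_params, "left")
        assert len(np.unique(s.codes)) == 36
        assert set(np.unique(s.orientations_deg)) <= set(np.arange(0, 180, 5.0))

    def test_single_block_is_a_permutation(self, stim_params):
        s = generate_orientation_sequence(1, 36, stim_params, "right")
        assert sorted(s.codes) == list(range(36))

    def test_30_frame_window_shows_any_orientation_at_most_twice(self, stim_params):
        s = generate_orientation_sequence(2, 100_000, stim_params, "left")
        w = sliding_window_view(s.codes, 30)
        worst = max(int((w == k).sum(axis=1).max()) for k in range(36))
        assert worst == 2

    def test_prefix_stability_and_bitwise_reproducibility(self, stim_params):
        a = generate_orientation_sequence(3, 5000, stim_params, "left", session_seed=9)
        b = generate_orientation_sequence(3, 200, stim_params, "left", session_seed=9)
        assert np.array_equal(a.codes[:200], b.codes)
        c = generate_orientation_sequence(3, 5000, stim_params, "left", session_seed=9)
        assert np.array_equal(a.codes, c.codes)

    def test_left_and_right_streams_differ(self, stim_params):
        left = generate_orientation_sequence(0, 500, stim_params, "left")
        right = generate_orientation_sequence(0, 500, stim_params, "right")
        assert not np.array_equal(left.codes, right.codes)

    def test_unknown_seed_raises(self, stim_params):
        with pytest.raises(ValueError, match="seed"):
            generate_orientation_sequence(5, 100, stim_params, "left")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed_id=st.integers(0, 4), n=st.integers(1, 400),
           side=st.sampled_from(["left", "right"]))
    def test_grid_closure(self, seed_id, n, side):
        s = generate_orientation_sequence(seed_id, n, StimulusParams(), side)
        deg = s.orientations_deg
        assert np.all((deg >= 0) & (deg <= 175))
        assert np.all(deg % 5 == 0)


class TestCoherentPeriod:
    def _zcp(self, stim_params, side="right", n=120):
        return generate_orientation_sequence(0, n, stim_params, side)

    def test_full_coherence_saturates_cp(self, stim_params, rng):
        s = embed_coherent_period(self._zcp(stim_params), 30, rng)
        cp = s.codes[s.cp_start_frame:s.cp_start_frame + 30]
        assert np.all(cp == stim_params.signal_code("right"))
        assert s.signal_mask.sum() == 30

    def test_zero_coherence_leaves_no_signal_frames(self, stim_params, rng):
        s = embed_coherent_period(self._zcp(stim_params), 0, rng)
        assert s.signal_mask.sum() == 0

    def test_right_side_signal_is_45_degrees(self, stim_params, rng):
        s = embed_coherent_period(self._zcp(stim_params), 12, rng)
        sig = s.codes[s.signal_mask] * stim_params.orientation_spacing
        assert np.all(sig == 45.0)

    def test_left_side_signal_is_135_degrees(self, stim_params, rng):
        s = embed_coherent_period(self._zcp(stim_params, side="left"), 12, rng)
        sig = s.codes[s.signal_mask] * stim_params.orientation_spacing
        assert np.all(sig == 135.0)

    def test_designed_signal_count_equals_coherence(self, stim_params, rng):
        for coh in (1, 5, 17):
            s = embed_coherent_period(self._zcp(stim_params), coh, rng)
            cp = s.codes[s.cp_start_frame:s.cp_start_frame + 30]
            # background CP frames are resampled away from the signal code
            assert int((cp == stim_params.signal_code("right")).sum()) == coh

    def test_200ms_post_cp_zcp_appended(self, stim_params, rng):
        s = embed_coherent_period(self._zcp(stim_params, n=80), 5, rng)
        assert s.n_frames == 80 + 30 + 20

    def test_out_of_range_coherence_raises(self, stim_params, rng):
        with pytest.raises(ValueError):
            embed_coherent_period(self._zcp(stim_params), 31, rng)


class TestSchedule:
    @pytest.fixture(scope="class")
    def schedule(self):
        rng = np.random.default_rng(23)
        cfg = ScheduleConfig()
        return cfg, build_session_schedule(cfg, rng, n_trials=6000)

    def test_catch_fraction_near_ten_percent(self, schedule):
        _, trials = schedule
        frac = np.mean([t.is_catch for t in trials])
        assert frac == pytest.approx(0.10, abs=0.015)

    def test_ab_change_side_is_even_split(self, schedule):
        _, trials = schedule
        ab = [t for t in trials if t.condition == "AB" and not t.is_catch]
        frac_rf = np.mean([t.change_side == "right" for t in ab])
        assert frac_rf == pytest.approx(0.5, abs=0.03)

    def test_blocks_randomized_in_complete_triplets(self, schedule):
        _, trials = schedule
        by_block = {}
        for t in trials:
            by_block[t.block_index] = t.condition
        order = [by_block[b] for b in sorted(by_block)]
        for i in range(0, len(order) - 3, 3):
            assert set(order[i:i + 3]) == set(CONDITIONS)

    def test_ab_coherences_one_frame_higher(self, schedule):
        cfg, trials = schedule
        ai = {t.coherence for t in trials if t.condition == "AI" and not t.is_catch}
        ab = {t.coherence for t in trials if t.condition == "AB" and not t.is_catch}
        assert ai == set(cfg.base_coherences)
        assert ab == {c + 1 for c in cfg.base_coherences}

    def test_cue_validity(self, schedule):
        cfg, trials = schedule
        for t in trials:
            if t.is_catch:
                assert t.change_side == "none"
            elif t.condition == "AI":
                assert t.change_side == cfg.rf_side
            elif t.condition == "AO":
                assert t.change_side == cfg.away_side

    def test_fewer_than_five_coherences_rejected(self):
        with pytest.raises(ValueError, match="coherences"):
            ScheduleConfig(base_coherences=(2, 3, 4))

    def test_trial_sequences_cover_trial_and_embed_change(self, schedule, rng):
        cfg, trials = schedule
        t0 = next(t for t in trials if not t.is_catch)
        seqs = trial_sequences(t0, cfg, rng, session_seed=1)
        changed = seqs[t0.change_side]
        assert changed.cp_start_frame == t0.zcp_frames
        assert changed.signal_mask.sum() == t0.coherence
        other = "left" if t0.change_side == "right" else "right"
        assert seqs[other].cp_start_frame is None


class TestParamValidation:
    def test_grid_must_tile_180(self):
        with pytest.raises(ValueError):
            StimulusParams(n_orientations=30)

    def test_signal_orientations_must_be_orthogonal(self):
        with pytest.raises(ValueError):
            StimulusParams(signal_orientation_left=135.0, signal_orientation_right=40.0)

    def test_trialspec_catch_consistency(self):
        with pytest.raises(ValueError):
            TrialSpec(condition="AI", seed_id=0, zcp_duration_s=1.0,
                      is_catch=True, change_side="right", coherence=3, block_index=0)
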