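"""Synthetic-experiment generator: attention states, spiking, behavior,
eye traces, LFP."""

import numpy as np
import pytest

from attnvar.csd import compute_csd
from attnvar.simulate import (
    ATTEND_AWAY,
    ATTEND_RF,
    AttentionModelParams,
    BehaviorParams,
    EyeParams,
    LfpParams,
    SyntheticUnit,
    default_population,
    sample_attention_state,
    simulate_behavior,
    simulate_eye_trace,
    simulate_lfp,
    simulate_spike_trains,
)
from attnvar.stimulus import StimulusParams, TrialSpec, generate_orientation_sequence


def _trial(cond="AB", zcp=1.0):
    return TrialSpec(condition=cond, seed_id=0, zcp_duration_s=zcp,
                     is_catch=True, change_side="none", coherence=0, block_index=0)


class TestAttentionState:
    def test_focused_conditions_are_constant(self, rng):
        p = AttentionModelParams()
        ai = sample_attention_state(_trial("AI"), p, rng, duration_ms=800)
        ao = sample_attention_state(_trial("AO"), p, rng, duration_ms=800)
        assert np.all(ai.state == ATTEND_RF)
        assert np.all(ao.state == ATTEND_AWAY)

    def test_ab_dwell_time_matches_switch_rate(self):
        # forced-switching trials: mean dwell ~ 250 ms at 4 Hz
        rng = np.random.default_rng(5)
        p = AttentionModelParams(within_trial_switch_hz=4.0, p_hold=0.0)
        dwells = []
        while len(dwells) < 10_000:
            s = sample_attention_state(_trial("AB", zcp=20.0), p, rng,
                                       duration_ms=20_000).state
            change = np.flatnonzero(np.diff(s.astype(int)) != 0)
            dwells.extend(np.diff(change))  # interior dwells only
        assert np.mean(dwells) == pytest.approx(250.0, rel=0.05)

    def test_ab_without_switching_reduces_to_focused_states(self, rng):
        p = AttentionModelParams(within_trial_switch_hz=0.0, ab_state_prior=1.0)
        s = sample_attention_state(_trial("AB"), p, rng, duration_ms=600)
        assert np.all(s.state == ATTEND_RF)
        p0 = AttentionModelParams(within_trial_switch_hz=0.0, ab_state_prior=0.0)
        s0 = sample_attention_state(_trial("AB"), p0, rng, duration_ms=600)
        assert np.all(s0.state == ATTEND_AWAY)

    def test_ab_initial_state_follows_prior(self):
        rng = np.random.default_rng(3)
        p = AttentionModelParams(within_trial_switch_hz=0.0, ab_state_prior=0.5)
        first = [sample_attention_state(_trial("AB"), p, rng, duration_ms=10).state[0]
                 for _ in range(2000)]
        assert np.mean(first) == pytest.approx(0.5, abs=0.04)


class TestSpikeTrains:
    def test_homogeneous_poisson_limit_has_unit_fano(self):
        rng = np.random.default_rng(8)
        unit = SyntheticUnit(preferred_orientation=0, amplitude=0.0, baseline_rate=25.0)
        seq = generate_orientation_sequence(0, 150, StimulusParams(), "right")
        p = AttentionModelParams()
        counts = []
        for _ in range(600):
            st = sample_attention_state(_trial("AO"), p, rng, duration_ms=1000)
            st.strength = 1.0  # remove shared jitter for the pure-Poisson limit
            t = simulate_spike_trains(_trial("AO"), [unit], st, seq, rng,
                                      params=p, duration_ms=1000)[0]
            counts.append(len(t))
        counts = np.asarray(counts, dtype=float)
        assert counts.mean() == pytest.approx(25.0, rel=0.05)
        assert counts.var(ddof=1) / counts.mean() == pytest.approx(1.0, abs=0.15)

    def test_attended_state_raises_rates(self):
        rng = np.random.default_rng(9)
        p = AttentionModelParams(gain_attended=1.3, focused_state_sd=0.0)
        units = default_population(6, rng)
        seq = generate_orientation_sequence(0, 150, StimulusParams(), "right")
        tot = {}
        for cond in ("AI", "AO"):
            n = 0
            for _ in range(150):
                st = sample_attention_state(_trial(cond), p, rng, duration_ms=1000)
                trains = simulate_spike_trains(_trial(cond), units, st, seq, rng,
                                               params=p, duration_ms=1000)
                n += sum(len(t) for t in trains)
            tot[cond] = n
        assert tot["AI"] > 1.05 * tot["AO"]

    def test_rates_are_rectified_never_negative(self, rng):
        unit = SyntheticUnit(preferred_orientation=0, baseline_rate=0.5,
                             amplitude=5.0, common_noise_loading=5.0)
        seq = generate_orientation_sequence(0, 150, StimulusParams(), "right")
        p = AttentionModelParams()
        st = sample_attention_state(_trial("AO"), p, rng, duration_ms=1000)
        trains = simulate_spike_trains(_trial("AO"), [unit], st, seq, rng, params=p,
                                       common_noise_sd=20.0, duration_ms=1000)
        assert np.all(trains[0] >= 0)


class TestBehavior:
    def test_saturating_coherence_always_detected(self):
        rng = np.random.default_rng(2)
        bp = BehaviorParams(fa_hazard_per_s=0.0, lapse=0.0)
        trial = TrialSpec(condition="AI", seed_id=0, zcp_duration_s=0.5,
                          is_catch=False, change_side="right", coherence=30, block_index=0)
        p = AttentionModelParams()
        hits = 0
        for _ in range(300):
            st = sample_attention_state(trial, p, rng, duration_ms=1000)
            out, rt, side = simulate_behavior(trial, st, bp, rng)
            hits += out == "hit"
            if out == "hit":
                assert 100.0 <= rt <= 500.0
                assert side == "right"
        assert hits == 300

    def test_zero_hazard_means_no_false_alarms(self):
        rng = np.random.default_rng(4)
        bp = BehaviorParams(fa_hazard_per_s=0.0)
        p = AttentionModelParams()
        outs = set()
        for _ in range(200):
            t = _trial("AB", zcp=3.0)
            st = sample_attention_state(t, p, rng)
            outs.add(simulate_behavior(t, st, bp, rng)[0])
        assert "false_alarm" not in outs

    def test_catch_trials_end_in_cr_or_fa_only(self):
        rng = np.random.default_rng(6)
        bp = BehaviorParams(fa_hazard_per_s=0.5)
        p = AttentionModelParams()
        for _ in range(200):
            t = _trial("AO", zcp=2.0)
            st = sample_attention_state(t, p, rng)
            out, _, _ = simulate_behavior(t, st, bp, rng)
            assert out in ("correct_rejection", "false_alarm")


class TestEyeTrace:
    def test_quiet_trace_has_no_detectable_events(self, rng):
        from attnvar.microsaccades import detect_microsaccades

        xy, ev = simulate_eye_trace(2000, EyeParams(jitter_sd_deg=0.01), rng, n_events=0)
        assert ev == []
        assert detect_microsaccades(xy) == []

    def test_planted_step_velocity(self, rng):
        xy, ev = simulate_eye_trace(
            3000, EyeParams(jitter_sd_deg=0.0, amp_range_deg=(0.5, 0.5),
                            dur_range_ms=(10.0, 10.0)), rng, n_events=1)
        e = ev[0]
        i0, i1 = int(e["onset_ms"]), int(e["offset_ms"])
        disp = np.linalg.norm(xy[i1] - xy[i0])
        assert disp == pytest.approx(0.5, abs=0.02)  # 0.5 deg in 10 ms = 50 deg/s


class TestLfp:
    def test_noiseless_dipole_sink_recovered(self, rng):
        lfp = simulate_lfp(300, 20, LfpParams(noise_sd_uv=0.0), rng)
        prof = compute_csd(lfp)
        assert prof.earliest_sink_channel == 20
        # sink polarity convention: sinks negative
        assert prof.csd.min() < 0
        assert int(np.unravel_index(np.argmin(prof.csd), prof.csd.shape)[0]) == 20

    def test_noise_only_sink_location_not_systematic(self):
        hits = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            lfp = simulate_lfp(200, 10, LfpParams(amp_uv=0.0, noise_sd_uv=2.0), rng)
            hits.append(compute_csd(lfp).earliest_sink_channel)
        # extremum location should spread over channels, not lock to one
        assert len(np.unique(hits)) > 5
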