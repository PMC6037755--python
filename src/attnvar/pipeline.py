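"""Session-level orchestration: simulation, analysis, inclusion criteria.

A session is simulated trial by trial: the scheduler proposes a trial, the
latent attention state is drawn, behavior decides the outcome (which feeds
back into block advancement — blocks end after 60 hits-plus-misses), and
spike trains, eye traces and the evoked LFP are generated.  Analysis then
runs the full chain — tuning, von Mises condition fits, block-wise
correlations and Fano factors, correlogram timescales, psychometrics,
microsaccades, CSD/laminar assignment — on correct trials, during the ZCP,
within the first 1000 ms (or 200 ms) after stimulus onset, with identical
trial masks shared by all analyses.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as beh
from . import correlations as corr
from . import csd as csdmod
from . import microsaccades as msmod
from . import rmstats
from . import timescale as tsmod
from . import tuning as tunmod
from . import vonmises as vmmod
from .simulate import (
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
from .stimulus import CONDITIONS, ScheduleConfig, TrialScheduler, trial_sequences

__all__ = [
    "SessionConfig",
    "SessionData",
    "SessionResults",
    "simulate_session",
    "run_session_analysis",
    "session_inclusion",
    "run_batch",
    "batch_statistics",
    "attention_params_for_eccentricity",
]


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to simulate and analyze one session."""

    session_seed: int = 0
    n_units: int = 10
    n_trials: int = 600
    eccentricity_deg: float = 6.0
    rf_side: str = "right"
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    attention: AttentionModelParams | None = None  # derived from eccentricity if None
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    windows_ms: tuple[int, ...] = (200, 1000)
    common_noise_sd: float = 3.0  # spikes/s, shared fast noise
    drift_walk_sd: float = 0.04  # per-block log-normal excitability walk
    sink_channel: int = 16
    n_perm_tuning: int = 200
    n_boot_psychometric: int = 200
    simulate_eyes: bool = True
    eye_params: EyeParams = field(default_factory=EyeParams)
    lfp_params: LfpParams = field(default_factory=LfpParams)
    inclusion_min_units: int = 10
    inclusion_min_seeds: int = 3

    def resolved_attention(self) -> AttentionModelParams:
        if self.attention is not None:
            return self.attention
        return attention_params_for_eccentricity(self.eccentricity_deg)

    def provenance(self) -> dict:
        d = dict(session_seed=self.session_seed, n_units=self.n_units,
                 n_trials=self.n_trials, eccentricity_deg=self.eccentricity_deg,
                 rf_side=self.rf_side, windows_ms=list(self.windows_ms))
        import hashlib

        h = hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]
        d["config_hash"] = h
        return d


def attention_params_for_eccentricity(ecc_deg: float) -> AttentionModelParams:
    """Attentional-state separation grows with the horizontal separation of
    the two stimuli: nearby stimuli can be attended jointly (small gain
    separation), distant ones force target switching (large separation)."""
    sep = max(0.0, 0.01 + 0.29 * (ecc_deg - 3.0) / 6.0)
    return AttentionModelParams(gain_attended=float(1.0 + sep))


@dataclass
class SessionData:
    """Simulated (or ingested) raw session contents."""

    config: SessionConfig
    units: list[SyntheticUnit]
    trials: pd.DataFrame  # schedule + outcome columns
    spikes: list[list[np.ndarray]]  # [trial][unit] spike times, ms from onset
    rf_codes: list[np.ndarray | None]  # per-trial RF-stimulus frame codes
    pre_counts: np.ndarray  # units x trials, 300 ms pre-onset counts
    eye_traces: list[np.ndarray | None]
    lfp: np.ndarray
    ground_truth: dict = field(default_factory=dict)


def simulate_session(config: SessionConfig) -> SessionData:
    """Generate a full synthetic session (deterministic given the config)."""
    ss = np.random.SeedSequence(config.session_seed)
    r_sched, r_pop, r_spk, r_beh, r_eye, r_lfp, r_seq = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    attn = config.resolved_attention()
    sched_cfg = replace(config.schedule, rf_side=config.rf_side, n_blocks=10**9)
    # offset-coupled units share the attentional separation of gain-coupled
    # ones: additive step scaled to the same fractional rate change
    units = default_population(
        config.n_units, r_pop,
        offset_attended=20.0 * (attn.gain_attended - attn.gain_unattended),
    )
    scheduler = TrialScheduler(sched_cfg, r_sched)
    pre_ms = 300
    rows, spikes, rf_codes, pre_counts, eye_traces = [], [], [], [], []
    states_truth, eye_truth = [], []
    log_drift = 0.0
    current_block = 0
    for _ in range(config.n_trials):
        if scheduler.block_index != current_block:
            current_block = scheduler.block_index
            log_drift += r_spk.normal(0.0, config.drift_walk_sd)
        trial = scheduler.next_trial()
        dur_ms = int(round(trial.zcp_duration_s * 1000)) + 500
        state = sample_attention_state(trial, attn, r_beh, duration_ms=dur_ms)
        outcome, rt, sacc_side = simulate_behavior(
            trial, state, config.behavior, r_beh, rf_side=config.rf_side
        )
        scheduler.record_outcome(outcome in ("hit", "miss"))
        seqs = trial_sequences(trial, sched_cfg, r_seq, session_seed=config.session_seed,
                               min_frames=dur_ms // 10 + 1)
        rf_seq = seqs[config.rf_side]
        correct = outcome in ("hit", "correct_rejection")
        drift = float(np.exp(log_drift))
        if correct:
            trains = simulate_spike_trains(
                trial, units, state, rf_seq, r_spk, params=attn, drift=drift,
                common_noise_sd=config.common_noise_sd, duration_ms=dur_ms,
            )
            pc = np.array([r_spk.poisson(u.baseline_rate * drift * pre_ms / 1000.0)
                           for u in units], dtype=float)
            codes = rf_seq.codes[: dur_ms // 10]
        else:
            trains, pc, codes = [np.array([]) for _ in units], np.full(config.n_units, np.nan), None
        if config.simulate_eyes and correct:
            xy, ev = simulate_eye_trace(dur_ms, config.eye_params, r_eye)
        else:
            xy, ev = None, []
        rows.append(dict(
            condition=trial.condition, seed_id=trial.seed_id, block=trial.block_index,
            zcp_ms=trial.zcp_duration_s * 1000.0, coherence=trial.coherence,
            change_side=trial.change_side, is_catch=trial.is_catch,
            outcome=outcome, rt_ms=rt, saccade_side=sacc_side, drift=drift,
            duration_ms=dur_ms,
        ))
        spikes.append(trains)
        rf_codes.append(codes)
        pre_counts.append(pc)
        eye_traces.append(xy)
        states_truth.append(state.state[:8].tolist())
        eye_truth.append(ev)
    lfp = np.mean(
        [simulate_lfp(300, config.sink_channel, config.lfp_params, r_lfp) for _ in range(10)],
        axis=0,
    )
    trials = pd.DataFrame(rows)
    trials.index.name = "trial"
    return SessionData(
        config=config, units=units, trials=trials, spikes=spikes, rf_codes=rf_codes,
        pre_counts=np.array(pre_counts).T, eye_traces=eye_traces, lfp=lfp,
        ground_truth=dict(states_head=states_truth, eye_events=eye_truth,
                          attention=asdict(attn)),
    )


def _analysis_mask(trials: pd.DataFrame, condition: str, window_ms: float) -> np.ndarray:
    """Correct trials of one condition with enough ZCP for the window —
    the single trial-selection rule shared by all analyses."""
    return (
        (trials["condition"] == condition)
        & trials["outcome"].isin(["hit", "correct_rejection"])
        & (trials["zcp_ms"] >= window_ms)
    ).to_numpy()


def _window_counts(data: SessionData, mask: np.ndarray, window_ms: float) -> np.ndarray:
    idx = np.flatnonzero(mask)
    out = np.zeros((data.config.n_units, len(idx)))
    for c, i in enumerate(idx):
        for u, t in enumerate(data.spikes[i]):
            out[u, c] = np.count_nonzero((t >= 0) & (t < window_ms))
    return out


@dataclass
class SessionResults:
    provenance: dict
    included: bool
    inclusion_reasons: list[str]
    behavior_summary: pd.DataFrame
    thresholds: dict
    mean_rate_hz: float
    rate_by_condition: dict
    tuning: pd.DataFrame
    modulation: pd.DataFrame
    rsc: pd.DataFrame  # condition x window mean r_sc
    fano: pd.DataFrame
    contrast_1000: float
    r_ccg: dict  # condition -> (tau, session-mean curve)
    sdf: dict
    microsaccades: dict
    layers: pd.DataFrame
    csd_sink_channel: int


def run_session_analysis(data: SessionData) -> SessionResults:
    """Run the full analysis chain on one session."""
    cfg = data.config
    trials = data.trials
    rng = np.random.default_rng(np.random.SeedSequence(cfg.session_seed).spawn(8)[-1])

    # --- behavior ---------------------------------------------------------
    beh_rows, thresholds = [], {}
    for cond in CONDITIONS:
        sub = trials[trials["condition"] == cond]
        summ = beh.session_behavior_summary(list(sub["outcome"]), list(sub["rt_ms"]))
        summ["condition"] = cond
        beh_rows.append(summ)
        hm = sub[sub["outcome"].isin(["hit", "miss"])]
        if hm["coherence"].nunique() >= 2 and hm["outcome"].nunique() == 2:
            fit = beh.fit_psychometric(
                hm["coherence"].to_numpy(), (hm["outcome"] == "hit").to_numpy().astype(float),
                n_boot=cfg.n_boot_psychometric, rng=rng,
            )
            thresholds[cond] = fit
    behavior_summary = pd.DataFrame(beh_rows).set_index("condition")

    # --- firing rates -----------------------------------------------------
    rate_by_condition = {}
    all_rates = []
    for cond in CONDITIONS:
        mask = _analysis_mask(trials, cond, 1000)
        if mask.sum() >= 3:
            counts = _window_counts(data, mask, 1000)
            rate_by_condition[cond] = float(counts.mean())
            all_rates.append(counts.mean(axis=1))
    mean_rate = float(np.mean(all_rates)) if all_rates else float("nan")

    # --- tuning -----------------------------------------------------------
    tuning_rows = []
    base_curves = {}
    cond_responses = {}
    for u in range(cfg.n_units):
        pooled = []
        per_cond: dict[str, list] = {c: [] for c in CONDITIONS}
        pre_list, post_list = [], []
        for i in range(len(trials)):
            codes = data.rf_codes[i]
            if codes is None:
                continue
            zcp_frames = int(trials["zcp_ms"].iloc[i] // 10)
            # full ZCP, not just the first second: with only 5 distinct seed
            # sequences the 36 x 15 design needs the longer trials to stay
            # identifiable
            n_use = min(zcp_frames, len(codes))
            counts = tunmod.bin_spike_counts(data.spikes[i][u], n_use, 10.0)
            pooled.append((counts, codes[:n_use]))
            per_cond[trials["condition"].iloc[i]].append((counts, codes[:n_use]))
            if np.isfinite(data.pre_counts[u, i]):
                pre_list.append(data.pre_counts[u, i])
                post_list.append(np.count_nonzero(
                    (data.spikes[i][u] >= 0) & (data.spikes[i][u] < 300)))
        tc = tunmod.estimate_tuning(pooled)
        base_curves[u] = tc
        p_resp = tunmod.visual_responsiveness(np.array(pre_list), np.array(post_list))
        p_tuned_cond = {}
        for cond in CONDITIONS:
            try:
                tc_c = tunmod.estimate_tuning(per_cond[cond])
                p_tuned_cond[cond] = tunmod.tuning_significance(
                    tc_c, per_cond[cond], n_perm=cfg.n_perm_tuning, rng=rng
                )
                cond_responses[(u, cond)] = tc_c.responses
            except ValueError:  # condition absent or too short in this session
                p_tuned_cond[cond] = float("nan")
        tc.p_tuned = max(p_tuned_cond.values())
        tuning_rows.append(dict(
            unit=u, latency_ms=tc.optimal_latency_ms, p_responsive=p_resp,
            **{f"p_tuned_{c}": p_tuned_cond[c] for c in CONDITIONS},
        ))
    tuning_df = pd.DataFrame(tuning_rows).set_index("unit")

    # --- von Mises condition modulation (AI vs AO, AO as reference) -------
    mod_rows = []
    for u in range(cfg.n_units):
        vm = vmmod.fit_von_mises(base_curves[u].responses)
        row = dict(unit=u, w3=vm.w3, w4=vm.w4,
                   pref_deg=vm.preferred_orientation_deg, converged=vm.converged)
        try:
            cm = vmmod.fit_condition_modulation(
                cond_responses[(u, "AO")], cond_responses[(u, "AI")], vm
            )
            row.update(f_stat=cm.f_stat, f_p=cm.f_p, classification=cm.classification)
        except (ValueError, KeyError):
            row.update(f_stat=np.nan, f_p=np.nan, classification="none")
        mod_rows.append(row)
    modulation = pd.DataFrame(mod_rows).set_index("unit")

    # --- correlations / Fano ---------------------------------------------
    rsc_rows, fano_rows = [], []
    contrast_1000 = float("nan")
    rsc_1000 = {}
    for window in cfg.windows_ms:
        for cond in CONDITIONS:
            mask = _analysis_mask(trials, cond, window)
            if mask.sum() < 6:
                continue
            counts = _window_counts(data, mask, window)
            seed = trials["seed_id"].to_numpy()[mask]
            block = trials["block"].to_numpy()[mask]
            try:
                z = corr.blockwise_zscore(counts, seed, block)
            except ValueError:
                continue
            mat = corr.pairwise_rsc_matrix(np.atleast_2d(z))
            iu = np.triu_indices(cfg.n_units, 1)
            vals = mat[iu]
            rsc_rows.append(dict(condition=cond, window_ms=window,
                                 r_sc=float(np.nanmean(vals)), n_trials=int(mask.sum())))
            if window == 1000:
                rsc_1000[cond] = float(np.nanmean(vals))
            fanos = [corr.fano_factor(counts[u], seed, block) for u in range(cfg.n_units)]
            fano_rows.append(dict(condition=cond, window_ms=window,
                                  fano=float(np.nanmean(fanos))))
    if len(rsc_1000) == 3:
        contrast_1000 = corr.correlation_contrast(
            rsc_1000["AI"], rsc_1000["AB"], rsc_1000["AO"])
    rsc_df = pd.DataFrame(rsc_rows)
    fano_df = pd.DataFrame(fano_rows)

    # --- correlogram timescale -------------------------------------------
    r_ccg = {}
    for cond in CONDITIONS:
        mask = _analysis_mask(trials, cond, 1000)
        idx = np.flatnonzero(mask)
        if len(idx) < 6:
            continue
        mats, seeds = [], []
        for i in idx:
            m = np.zeros((cfg.n_units, 1000))
            for u, t in enumerate(data.spikes[i]):
                tt = t[(t >= 0) & (t < 1000)].astype(int)
                np.add.at(m[u], tt, 1.0)
            mats.append(m)
            seeds.append(trials["seed_id"].iloc[i])
        try:
            res = tsmod.correlogram_set(mats, seeds, window_ms=1000)
        except ValueError:
            continue
        tau = np.arange(1, 1001)
        curves = []
        for j in range(cfg.n_units):
            for k in range(j + 1, cfg.n_units):
                _, c = tsmod.cumulative_r_ccg(res, j, k, tau)
                curves.append(c)
        r_ccg[cond] = (tau, np.nanmean(curves, axis=0))

    # --- spike density functions -----------------------------------------
    sdf_input: dict[tuple[str, int], list[np.ndarray]] = {}
    for i in range(len(trials)):
        if trials["outcome"].iloc[i] != "hit":
            continue
        key = (trials["condition"].iloc[i], int(trials["seed_id"].iloc[i]))
        pooled_train = np.concatenate([data.spikes[i][u] for u in range(cfg.n_units)])
        sdf_input.setdefault(key, []).append(pooled_train)
    sdf = tunmod.spike_density_function(sdf_input, duration_ms=1000) if sdf_input else {}

    # --- microsaccades ----------------------------------------------------
    ms_events: dict[str, list] = {c: [] for c in CONDITIONS}
    ms_time: dict[str, float] = {c: 0.0 for c in CONDITIONS}
    if cfg.simulate_eyes:
        for i in range(len(trials)):
            xy = data.eye_traces[i]
            if xy is None:
                continue
            zcp_n = int(trials["zcp_ms"].iloc[i])
            cond = trials["condition"].iloc[i]
            evs = msmod.detect_microsaccades(xy[:zcp_n])
            ms_events[cond].extend(evs)
            ms_time[cond] += zcp_n / 1000.0
    ms_norm, ms_dirs = msmod.microsaccade_stats(ms_events, ms_time)
    microsaccades = dict(normalized_rate=ms_norm, direction_props=ms_dirs,
                         n_events={c: len(v) for c, v in ms_events.items()})

    # --- laminar ----------------------------------------------------------
    profile = csdmod.compute_csd(data.lfp)
    depths = np.array([u.depth_um for u in data.units])
    labels = csdmod.assign_layers(depths)
    layers = pd.DataFrame(dict(unit=np.arange(cfg.n_units), depth_um=depths, layer=labels))

    results = SessionResults(
        provenance=cfg.provenance(), included=False, inclusion_reasons=[],
        behavior_summary=behavior_summary, thresholds=thresholds,
        mean_rate_hz=mean_rate, rate_by_condition=rate_by_condition,
        tuning=tuning_df, modulation=modulation, rsc=rsc_df, fano=fano_df,
        contrast_1000=contrast_1000, r_ccg=r_ccg, sdf=sdf,
        microsaccades=microsaccades, layers=layers,
        csd_sink_channel=profile.earliest_sink_channel,
    )
    results.included, results.inclusion_reasons = session_inclusion(data, results)
    return results


def session_inclusion(data: SessionData, results: SessionResults, alpha: float = 0.05):
    """Dataset inclusion rule: at least ``inclusion_min_units`` units that
    are visually responsive and significantly orientation tuned in every
    attention condition, and at least ``inclusion_min_seeds`` seeds with >= 3
    correct, sufficiently long trials in every condition."""
    cfg = data.config
    t = results.tuning
    qualifying = (
        (t["p_responsive"] < alpha)
        & np.all([t[f"p_tuned_{c}"] < alpha for c in CONDITIONS], axis=0)
    ).sum()
    reasons = []
    if qualifying < cfg.inclusion_min_units:
        reasons.append(f"only {int(qualifying)} qualifying units "
                       f"(need {cfg.inclusion_min_units})")
    valid_seeds = 0
    for s in range(cfg.schedule.params.n_seeds):
        ok = True
        for cond in CONDITIONS:
            mask = _analysis_mask(data.trials, cond, 1000)
            n = int((data.trials["seed_id"].to_numpy()[mask] == s).sum())
            if n < 3:
                ok = False
        valid_seeds += ok
    if valid_seeds < cfg.inclusion_min_seeds:
        reasons.append(f"only {valid_seeds} valid seeds (need {cfg.inclusion_min_seeds})")
    return len(reasons) == 0, reasons


def run_batch(
    n_sessions: int = 30,
    base_seed: int = 0,
    ecc_range: tuple[float, float] = (3.0, 9.0),
    **config_overrides,
) -> list[tuple[SessionData, SessionResults]]:
    """Simulate and analyze a batch of sessions with eccentricities spread
    over ``ecc_range`` (the Fig-5d-style separation manipulation)."""
    eccs = np.linspace(*ecc_range, n_sessions)
    out = []
    for i in range(n_sessions):
        seed = int(np.random.SeedSequence(entropy=(base_seed, i)).generate_state(1)[0] % (2**31))
        cfg = SessionConfig(session_seed=seed, eccentricity_deg=float(eccs[i]),
                            **config_overrides)
        data = simulate_session(cfg)
        out.append((data, run_session_analysis(data)))
    return out


def batch_statistics(batch: list[tuple[SessionData, SessionResults]]) -> dict:
    """Cross-session statistics mirroring the study's session-level tests."""
    rows = []
    for data, res in batch:
        row = dict(eccentricity=data.config.eccentricity_deg,
                   contrast=res.contrast_1000, mean_rate=res.mean_rate_hz)
        for cond in CONDITIONS:
            sub = res.rsc[(res.rsc["condition"] == cond) & (res.rsc["window_ms"] == 1000)]
            row[f"rsc_{cond}"] = float(sub["r_sc"].iloc[0]) if len(sub) else np.nan
            fit = res.thresholds.get(cond)
            row[f"thr_{cond}"] = fit.threshold_50 if fit and not fit.degenerate else np.nan
            row[f"rate_{cond}"] = res.rate_by_condition.get(cond, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    out = dict(sessions=df)
    rsc_mat = df[[f"rsc_{c}" for c in CONDITIONS]].to_numpy()
    if np.isfinite(rsc_mat).all():
        out["rsc_anova"] = rmstats.rm_anova(rsc_mat)
        t, dfree, p = rmstats.ab_contrast_test(df["rsc_AI"], df["rsc_AB"], df["rsc_AO"])
        out["ab_contrast"] = dict(t=t, df=dfree, p=p)
    thr_mat = df[[f"thr_{c}" for c in CONDITIONS]].to_numpy()
    ok = np.isfinite(thr_mat).all(axis=1)
    if ok.sum() >= 3:
        out["threshold_anova"] = rmstats.rm_anova(thr_mat[ok])
        out["threshold_means"] = {c: float(np.nanmean(df[f"thr_{c}"])) for c in CONDITIONS}
    ok_c = np.isfinite(df["contrast"]) & np.isfinite(df["eccentricity"])
    if ok_c.sum() >= 3:
        r, t, p = corr.eccentricity_trend(df.loc[ok_c, "contrast"],
                                          df.loc[ok_c, "eccentricity"])
        out["eccentricity_trend"] = dict(r=r, t=t, p=p)
    # grand-average r_CCG curves per condition
    curves: dict[str, list[np.ndarray]] = {}
    for _, res in batch:
        for cond, (tau, c) in res.r_ccg.items():
            curves.setdefault(cond, []).append(c)
    out["r_ccg_mean"] = {c: np.nanmean(v, axis=0) for c, v in curves.items()}
    return out
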