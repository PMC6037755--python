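"""Synthetic experiment generator: attention states, spiking populations,
behavior, eye traces and laminar LFPs.

The generative model embodies the attentional-fluctuation hypothesis: each
trial carries a latent attention state s(t) indicating which stimulus
currently receives the attentional gain.  In the focused conditions (AI, AO)
the state is constant within and across trials, up to a small shared
trial-to-trial jitter of attentional strength.  In the Attend-Both condition
the target is drawn at random at trial start and then either held for the
whole trial (probability ``p_hold``) or revisited by a telegraph process
switching on average every 1/``within_trial_switch_hz`` seconds (~4 Hz, i.e.
every 250 ms).  Because all units sharing a receptive field gain-modulate
together, these state fluctuations induce correlated spike-count variability
that is strongest in AB and builds up over hundreds of milliseconds, while a
fast shared noise process produces the short-timescale correlations common
to all conditions.

Units are orientation tuned (von Mises on the doubled angle), respond at a
fixed latency, and fire as inhomogeneous Poisson processes at 1 ms
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import OrientationSequence, TrialSpec

__all__ = [
    "AttentionModelParams",
    "SyntheticUnit",
    "AttentionStateTrace",
    "BehaviorParams",
    "EyeParams",
    "LfpParams",
    "default_population",
    "sample_attention_state",
    "von_mises_tuning",
    "unit_rate",
    "simulate_spike_trains",
    "simulate_behavior",
    "simulate_eye_trace",
    "simulate_lfp",
]

ATTEND_RF = 1
ATTEND_AWAY = 0


@dataclass(frozen=True)
class AttentionModelParams:
    """Latent attention-state model.

    ``gain_attended``/``gain_unattended`` multiply the tuned response of a
    gain-coupled unit when its stimulus is / is not the attentional target.
    Their separation controls how much variance attention-state fluctuations
    inject into the population.  ``focused_state_sd`` is the SD of a shared
    log-normal trial-to-trial jitter of attentional strength (present in all
    conditions).  ``p_hold`` is the probability that an AB trial commits to
    its initial target for the whole trial instead of switching.
    """

    gain_attended: float = 1.14
    gain_unattended: float = 1.0
    within_trial_switch_hz: float = 4.0
    focused_state_sd: float = 0.03
    ab_state_prior: float = 0.5
    p_hold: float = 0.5

    def __post_init__(self) -> None:
        if not self.gain_attended >= self.gain_unattended > 0:
            raise ValueError("require gain_attended >= gain_unattended > 0")
        if self.within_trial_switch_hz < 0:
            raise ValueError("switch rate must be >= 0")
        if not 0.0 <= self.ab_state_prior <= 1.0:
            raise ValueError("ab_state_prior must be a probability")


@dataclass(frozen=True)
class SyntheticUnit:
    """One orientation-tuned unit.

    ``attention_coupling`` is 'gain', 'offset' or 'mixed'; ``offset_attended``
    is the additive rate change (spikes/s) at full attentional engagement for
    offset-coupled units.  ``depth_um`` is signed depth relative to the first
    layer-5 channel (negative = more superficial), on the 60 um channel grid.
    """

    preferred_orientation: float
    tuning_width: float = 1.5  # von Mises concentration (doubled angle)
    baseline_rate: float = 8.0
    amplitude: float = 38.0
    latency_ms: float = 50.0
    attention_coupling: str = "mixed"
    offset_attended: float = 2.5
    depth_um: float = 0.0
    common_noise_loading: float = 1.0

    def __post_init__(self) -> None:
        if self.attention_coupling not in ("gain", "offset", "mixed"):
            raise ValueError("attention_coupling must be gain|offset|mixed")


@dataclass
class AttentionStateTrace:
    """Per-ms latent state (1 = RF stimulus attended) and shared strength
    jitter for one trial."""

    state: np.ndarray  # uint8 per ms
    strength: float  # shared multiplicative jitter, ~1

    @property
    def duration_ms(self) -> int:
        return len(self.state)


def default_population(
    n_units: int,
    rng: np.random.Generator,
    gain_fraction: float = 0.32,
    offset_fraction: float = 0.20,
    baseline_rate: float = 8.0,
    amplitude: float = 38.0,
    tuning_width: float = 1.5,
    latency_ms: float = 50.0,
    offset_attended: float = 2.5,
) -> list[SyntheticUnit]:
    """Roster of tuned units with preferred orientations spread over the
    grid, attention-coupling classes in the observed population proportions
    (~32% pure gain, ~20% pure offset, remainder mixed) and depths spanning
    the 32-channel probe."""
    prefs = (np.arange(n_units) * 180.0 / n_units + rng.uniform(0, 5, n_units)) % 180.0
    n_gain = int(round(gain_fraction * n_units))
    n_off = int(round(offset_fraction * n_units))
    coupling = ["gain"] * n_gain + ["offset"] * n_off + ["mixed"] * (n_units - n_gain - n_off)
    rng.shuffle(coupling)
    depths = rng.choice(np.arange(-16, 16) * 60.0, size=n_units, replace=n_units > 32)
    units = []
    for i in range(n_units):
        units.append(
            SyntheticUnit(
                preferred_orientation=float(prefs[i]),
                tuning_width=tuning_width * float(rng.uniform(0.8, 1.2)),
                baseline_rate=baseline_rate * float(rng.uniform(0.7, 1.3)),
                amplitude=amplitude * float(rng.uniform(0.7, 1.3)),
                latency_ms=latency_ms,
                attention_coupling=coupling[i],
                offset_attended=offset_attended,
                depth_um=float(depths[i]),
            )
        )
    return units


def sample_attention_state(
    trial: TrialSpec,
    params: AttentionModelParams,
    rng: np.random.Generator,
    duration_ms: int | None = None,
) -> AttentionStateTrace:
    """Latent attention state for one trial.

    AI: RF stimulus attended throughout; AO: away stimulus attended.  AB:
    initial target ~ Bernoulli(ab_state_prior); with probability ``p_hold``
    the target is held for the whole trial, otherwise it switches as a
    telegraph process with exponential dwell times of mean
    1000/``within_trial_switch_hz`` ms.
    """
    if duration_ms is None:
        duration_ms = int(round(trial.zcp_duration_s * 1000)) + 500
    strength = float(np.exp(rng.normal(0.0, params.focused_state_sd)))
    if trial.condition == "AI":
        state = np.full(duration_ms, ATTEND_RF, dtype=np.uint8)
    elif trial.condition == "AO":
        state = np.full(duration_ms, ATTEND_AWAY, dtype=np.uint8)
    else:
        s0 = ATTEND_RF if rng.random() < params.ab_state_prior else ATTEND_AWAY
        state = np.full(duration_ms, s0, dtype=np.uint8)
        switching = params.within_trial_switch_hz > 0 and rng.random() >= params.p_hold
        if switching:
            mean_dwell = 1000.0 / params.within_trial_switch_hz
            t, s = 0.0, s0
            while t < duration_ms:
                dwell = rng.exponential(mean_dwell)
                t_end = min(duration_ms, int(np.ceil(t + dwell)))
                state[int(t):t_end] = s
                s = ATTEND_RF + ATTEND_AWAY - s
                t += dwell
    return AttentionStateTrace(state=state, strength=strength)


def von_mises_tuning(orientation_deg, pref_deg: float, kappa: float):
    """Normalized tuning profile exp(kappa*(cos(2*(theta-pref))-1)) in [0,1];
    the doubled angle maps the 180-deg orientation circle onto one von Mises
    period."""
    d = np.deg2rad(2.0 * (np.asarray(orientation_deg, dtype=float) - pref_deg))
    return np.exp(kappa * (np.cos(d) - 1.0))


def _gain_offset(unit: SyntheticUnit, params: AttentionModelParams, attended, strength):
    """Per-ms multiplicative gain and additive offset (spikes/s) for a unit
    given the attended indicator array for its stimulus."""
    a = attended.astype(float) * strength
    g_lo, g_hi = params.gain_unattended, params.gain_attended
    if unit.attention_coupling == "gain":
        gain = g_lo + (g_hi - g_lo) * a
        off = np.zeros_like(a)
    elif unit.attention_coupling == "offset":
        gain = np.full_like(a, g_lo)
        off = unit.offset_attended * a
    else:  # mixed: half-strength each
        gain = g_lo + 0.5 * (g_hi - g_lo) * a
        off = 0.5 * unit.offset_attended * a
    return gain, off


def unit_rate(
    unit: SyntheticUnit,
    rf_sequence: OrientationSequence,
    state: AttentionStateTrace,
    params: AttentionModelParams,
    duration_ms: int,
    drift: float = 1.0,
    common_noise: np.ndarray | None = None,
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) at 1 ms resolution.

    lambda(t) = drift * [offset(s) + gain(s)*amplitude*VM(theta(t-latency))
                         + baseline + loading*z(t)]_+
    """
    t = np.arange(duration_ms)
    t_stim = t - int(round(unit.latency_ms))
    theta = np.where(
        t_stim >= 0,
        rf_sequence.orientation_at_ms(np.maximum(t_stim, 0)) * rf_sequence.params.orientation_spacing,
        np.nan,
    )
    vm = np.where(
        np.isnan(theta), 0.0, von_mises_tuning(np.nan_to_num(theta), unit.preferred_orientation, unit.tuning_width)
    )
    attended = state.state[:duration_ms] == ATTEND_RF
    gain, off = _gain_offset(unit, params, attended, state.strength)
    lam = off + gain * unit.amplitude * vm + unit.baseline_rate
    if common_noise is not None:
        lam = lam + unit.common_noise_loading * common_noise[:duration_ms]
    return np.clip(drift * lam, 0.0, None)


def simulate_spike_trains(
    trial: TrialSpec,
    units: list[SyntheticUnit],
    state: AttentionStateTrace,
    rf_sequence: OrientationSequence,
    rng: np.random.Generator,
    params: AttentionModelParams | None = None,
    drift: float = 1.0,
    common_noise_sd: float = 0.0,
    common_noise_tau_ms: float = 30.0,
    duration_ms: int | None = None,
) -> list[np.ndarray]:
    """Inhomogeneous-Poisson spike times (ms from stimulus onset) per unit.

    Spikes are drawn per 1 ms bin (Bernoulli approximation, exact for the
    rates used here).  ``common_noise_sd`` adds a shared Ornstein-Uhlenbeck
    rate fluctuation (spikes/s) with time constant ``common_noise_tau_ms``
    driving fast correlations identical across attention conditions.
    """
    params = params or AttentionModelParams()
    if duration_ms is None:
        duration_ms = min(state.duration_ms, rf_sequence.n_frames * 10)
    z = None
    if common_noise_sd > 0:
        z = _ou_process(duration_ms, common_noise_sd, common_noise_tau_ms, rng)
    rates = np.stack(
        [unit_rate(u, rf_sequence, state, params, duration_ms, drift, z) for u in units]
    )
    p = np.clip(rates * 1e-3, 0.0, 1.0)
    spikes_mat = rng.random(p.shape) < p
    return [np.flatnonzero(row).astype(float) for row in spikes_mat]


def _ou_process(n: int, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import lfilter

    a = np.exp(-1.0 / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1 - a * a), size=n)
    innov[0] = rng.normal(0.0, sd)
    return lfilter([1.0], [1.0, -a], innov)


@dataclass(frozen=True)
class BehaviorParams:
    """Psychophysical observer.

    Detection probability is logistic in coherence with location
    ``threshold_attended`` when the changed stimulus is the attentional
    target at CP onset and ``threshold_unattended`` otherwise.  False alarms
    arise from a constant hazard during the ZCP.
    """

    threshold_attended: float = 3.2
    threshold_unattended: float = 5.5
    slope: float = 0.8
    fa_hazard_per_s: float = 0.25
    lapse: float = 0.02
    rt_shape: float = 5.0
    rt_scale_ms: float = 50.0
    rt_min_ms: float = 100.0  # responses locked out in first 100 ms of CP
    rt_max_ms: float = 500.0  # CP (300) + 200 ms post-CP ZCP


def simulate_behavior(
    trial: TrialSpec,
    state: AttentionStateTrace,
    params: BehaviorParams,
    rng: np.random.Generator,
    rf_side: str = "right",
) -> tuple[str, float | None, str | None]:
    """Outcome, reaction time (ms from CP onset) and saccade side.

    Returns (outcome, rt_ms, saccade_side) with outcome in
    hit|miss|correct_rejection|false_alarm.  Catch trials can end only in
    correct_rejection or false_alarm.
    """
    zcp_ms = trial.zcp_duration_s * 1000.0
    # false alarm: first event of a constant-hazard process within the ZCP
    if params.fa_hazard_per_s > 0:
        t_fa = rng.exponential(1000.0 / params.fa_hazard_per_s)
        if t_fa < zcp_ms:
            side = "left" if rng.random() < 0.5 else "right"
            return "false_alarm", None, side
    if trial.is_catch:
        return "correct_rejection", None, None
    # is the changed stimulus the attentional target at CP onset?
    cp_onset = min(int(zcp_ms), state.duration_ms - 1)
    rf_attended = state.state[cp_onset] == ATTEND_RF
    change_on_rf = trial.change_side == rf_side
    attended = rf_attended if change_on_rf else not rf_attended
    if trial.condition in ("AI", "AO"):
        attended = True  # 100% valid cue: subject attends the only relevant stimulus
    thr = params.threshold_attended if attended else params.threshold_unattended
    p_detect = (1 - params.lapse) / (1.0 + np.exp(-(trial.coherence - thr) / params.slope))
    if rng.random() < p_detect:
        rt = params.rt_min_ms + float(rng.gamma(params.rt_shape, params.rt_scale_ms))
        rt = min(rt, params.rt_max_ms - 1e-6)
        return "hit", rt, trial.change_side
    return "miss", None, None


@dataclass(frozen=True)
class EyeParams:
    """Fixational eye-trace generator (1 kHz sampling)."""

    fs_hz: float = 1000.0
    jitter_sd_deg: float = 0.01
    jitter_tau_ms: float = 20.0
    microsaccade_rate_hz: float = 1.0
    amp_range_deg: tuple[float, float] = (0.2, 1.0)
    dur_range_ms: tuple[float, float] = (10.0, 30.0)


def simulate_eye_trace(
    duration_ms: int,
    params: EyeParams,
    rng: np.random.Generator,
    n_events: int | None = None,
):
    """2-D gaze trace with planted microsaccades.

    Returns (xy, events) where xy is (n_samples, 2) in degrees and events is
    a list of dicts with ground-truth onset/offset (ms), amplitude (deg) and
    direction (deg) for detector validation.
    """
    n = int(duration_ms * params.fs_hz / 1000.0)
    dt_ms = 1000.0 / params.fs_hz
    xy = np.stack(
        [_ou_process(n, params.jitter_sd_deg, params.jitter_tau_ms / dt_ms, rng) for _ in range(2)],
        axis=1,
    )
    if n_events is None:
        n_events = rng.poisson(params.microsaccade_rate_hz * duration_ms / 1000.0)
    events = []
    if n_events > 0:
        dur_lo, dur_hi = params.dur_range_ms
        margin = int(np.ceil(dur_hi / dt_ms)) + 2
        starts = np.sort(rng.choice(max(1, n - 2 * margin), size=n_events, replace=False)) + margin
        last_end = -10**9
        for s in starts:
            if s < last_end + int(50 / dt_ms):  # enforce >=50 ms separation
                continue
            amp = float(rng.uniform(*params.amp_range_deg))
            dur = float(rng.uniform(dur_lo, dur_hi))
            ndur = max(2, int(round(dur / dt_ms)))
            direc = float(rng.uniform(0.0, 360.0))
            step = amp * np.array([np.cos(np.deg2rad(direc)), np.sin(np.deg2rad(direc))])
            ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ndur)))  # smooth step
            xy[s:s + ndur] += ramp[:, None] * step[None, :]
            xy[s + ndur:] += step[None, :]
            events.append(
                dict(onset_ms=s * dt_ms, offset_ms=(s + ndur) * dt_ms,
                     amplitude_deg=amp, direction_deg=direc)
            )
            last_end = s + ndur
    return xy, events


@dataclass(frozen=True)
class LfpParams:
    """Laminar LFP generator: 32 channels, 60 um spacing, one dipolar
    stimulus-evoked sink with flanking sources."""

    n_channels: int = 32
    spacing_um: float = 60.0
    sink_width_ch: float = 1.5
    amp_uv: float = 80.0
    onset_ms: float = 40.0
    rise_ms: float = 15.0
    decay_ms: float = 60.0
    noise_sd_uv: float = 2.0
    noise_smooth_ch: float = 1.0


def simulate_lfp(
    duration_ms: int,
    sink_channel: int,
    params: LfpParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Channel x time LFP (uV) whose CSD (negative second spatial
    difference) has its earliest sink extremum at ``sink_channel``."""
    from scipy.ndimage import gaussian_filter1d

    ch = np.arange(params.n_channels)
    t = np.arange(duration_ms)
    # CSD target profile: Gaussian sink at sink_channel (negative), flanked
    # by sources from the second derivative of a Gaussian potential profile.
    # Build the potential directly as a Gaussian bump whose curvature at the
    # center yields a sink under CSD_j = -(V_{j-1}-2V_j+V_{j+1})/h^2:
    # with V = -A*g(ch), the discrete second difference at the peak is
    # positive, so CSD = -(...)/h^2 is negative there (a sink).
    spatial = -np.exp(-0.5 * ((ch - sink_channel) / params.sink_width_ch) ** 2)
    temporal = np.where(
        t > params.onset_ms,
        (1 - np.exp(-(t - params.onset_ms) / params.rise_ms))
        * np.exp(-(t - params.onset_ms) / params.decay_ms),
        0.0,
    )
    lfp = params.amp_uv * spatial[:, None] * temporal[None, :]
    if params.noise_sd_uv > 0:
        noise = rng.normal(0.0, params.noise_sd_uv, size=lfp.shape)
        noise = gaussian_filter1d(noise, params.noise_smooth_ch, axis=0, mode="nearest")
        lfp = lfp + noise
    return lfp
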