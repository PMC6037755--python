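"""Dynamic orientation-noise stimulus and session schedule generation.

The change-detection task shows two Gabor patches whose orientations change
every 10 ms frame, drawn from 36 orientations spaced 5 degrees apart on
[0, 175].  During the zero-coherence period (ZCP) the orientation stream is a
concatenation of random permutation blocks: each orientation is shown once
before any may repeat, which caps the number of chance occurrences of any
orientation in a 300 ms (30-frame) window at two.  After an exponentially
distributed ZCP one stimulus enters a 300 ms coherent period (CP) in which a
"signal" orientation (135 deg left, 45 deg right) is shown on ``coherence``
of the 30 frames, followed by a further 200 ms of ZCP for the response.

Attention is cued in blocks: Attend-In (AI, change always on the
receptive-field stimulus), Attend-Out (AO, change always on the opposite
stimulus) and Attend-Both (AB, 50/50).  Blocks run until 60 hit-or-miss
trials are counted and are randomized in sets of three.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StimulusParams",
    "OrientationSequence",
    "TrialSpec",
    "ScheduleConfig",
    "TrialScheduler",
    "calibrate_zcp_rate",
    "truncated_exp_mean",
    "sample_zcp_duration",
    "generate_orientation_sequence",
    "embed_coherent_period",
    "build_session_schedule",
    "trial_sequences",
    "schedule_to_table",
    "CONDITIONS",
]

CONDITIONS = ("AI", "AB", "AO")


@dataclass(frozen=True)
class StimulusParams:
    """Task stimulus parameters.

    Durations are in the units of the field name suffix; orientations in
    degrees on the 180-degree circle.
    """

    n_orientations: int = 36
    orientation_spacing: float = 5.0
    frame_ms: float = 10.0
    cp_frames: int = 30
    post_cp_ms: float = 200.0
    zcp_min_s: float = 0.01
    zcp_mean_s: float = 2.17
    zcp_max_s: float = 5.0
    signal_orientation_left: float = 135.0
    signal_orientation_right: float = 45.0
    n_seeds: int = 5
    catch_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_orientations * self.orientation_spacing != 180.0:
            raise ValueError("orientation grid must tile 180 degrees")
        if not (self.zcp_min_s <= self.zcp_mean_s <= self.zcp_max_s):
            raise ValueError("ZCP durations must satisfy min <= mean <= max")
        grid = self.orientation_grid
        for sig in (self.signal_orientation_left, self.signal_orientation_right):
            if not np.any(np.isclose(grid, sig)):
                raise ValueError(f"signal orientation {sig} not on the grid")
        if abs(self.signal_orientation_left - self.signal_orientation_right) % 180 != 90:
            raise ValueError("left/right signal orientations must be orthogonal")
        if not 0.0 <= self.catch_fraction <= 1.0:
            raise ValueError("catch_fraction must be a probability")

    @property
    def orientation_grid(self) -> np.ndarray:
        return np.arange(self.n_orientations) * self.orientation_spacing

    def signal_code(self, side: str) -> int:
        sig = {"left": self.signal_orientation_left, "right": self.signal_orientation_right}[side]
        return int(round(sig / self.orientation_spacing))

    @property
    def post_cp_frames(self) -> int:
        return int(round(self.post_cp_ms / self.frame_ms))


@dataclass
class OrientationSequence:
    """Frame-indexed orientation stream for one stimulus on one trial.

    ``codes`` are orientation indices (0..35 -> 0..175 deg in 5-deg steps).
    ``signal_mask`` flags frames designed to carry the signal orientation.
    """

    codes: np.ndarray
    seed_id: int
    side: str
    zcp_frames: int
    cp_start_frame: int | None = None
    signal_mask: np.ndarray | None = None
    params: StimulusParams = field(default_factory=StimulusParams)

    @property
    def orientations_deg(self) -> np.ndarray:
        return self.codes * self.params.orientation_spacing

    @property
    def n_frames(self) -> int:
        return len(self.codes)

    def orientation_at_ms(self, t_ms: np.ndarray) -> np.ndarray:
        """Orientation code shown at each time (ms from stimulus onset)."""
        f = np.asarray(t_ms, dtype=np.int64) // int(self.params.frame_ms)
        f = np.clip(f, 0, self.n_frames - 1)
        return self.codes[f]


def truncated_exp_mean(rate: float, lo: float, hi: float) -> float:
    """Mean of an exponential(rate) truncated to [lo, hi] (closed form)."""
    span = hi - lo
    z = rate * span
    # lo + (1/rate) - span * exp(-z) / (1 - exp(-z)), stable for small z
    if z < 1e-12:
        return lo + span / 2.0
    return lo + 1.0 / rate - span * np.exp(-z) / (1.0 - np.exp(-z))


def calibrate_zcp_rate(params: StimulusParams) -> float:
    """Rate of the underlying exponential such that the truncated mean
    equals ``zcp_mean_s``.

    The printed min/mean/max describe what subjects experienced, i.e. the
    truncated distribution, so the naive rate 1/mean would undershoot.
    """
    lo, hi, target = params.zcp_min_s, params.zcp_max_s, params.zcp_mean_s
    f = lambda r: truncated_exp_mean(r, lo, hi) - target
    # truncated mean is decreasing in rate; bracket generously
    return brentq(f, 1e-6, 1e3, xtol=1e-12, rtol=1e-14)


def sample_zcp_duration(
    params: StimulusParams,
    rng: np.random.Generator,
    size: int | None = None,
    rate: float | None = None,
):
    """Draw ZCP durations (s) from the calibrated bounded exponential.

    Inverse-CDF sampling of the exponential conditioned on [min, max].
    """
    if rate is None:
        rate = calibrate_zcp_rate(params)
    lo, hi = params.zcp_min_s, params.zcp_max_s
    u = rng.random(size)
    mass = 1.0 - np.exp(-rate * (hi - lo))
    d = lo - np.log1p(-u * mass) / rate
    return np.clip(d, lo, hi)


def _sequence_rng(seed_id: int, side: str, session_seed: int) -> np.random.Generator:
    side_code = {"left": 0, "right": 1}[side]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=session_seed, spawn_key=(1000 + seed_id, side_code))
    )


def generate_orientation_sequence(
    seed_id: int,
    n_frames: int,
    params: StimulusParams | None = None,
    side: str = "left",
    session_seed: int = 0,
) -> OrientationSequence:
    """Deterministic permutation-block orientation stream.

    Concatenates independent uniform permutations of the 36 orientations, so
    each orientation appears exactly once per 36-frame block (hence at most
    twice in any 30-frame window).  The first ``k`` frames are identical for
    any requested length >= k, which is what makes same-seed trials of
    different durations "identical repetitions" of the same stimulus.
    """
    params = params or StimulusParams()
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not 0 <= seed_id < params.n_seeds:
        raise ValueError(f"unknown seed_id {seed_id}; session has {params.n_seeds} seeds")
    rng = _sequence_rng(seed_id, side, session_seed)
    n_blocks = -(-n_frames // params.n_orientations)
    blocks = [rng.permutation(params.n_orientations) for _ in range(n_blocks)]
    codes = np.concatenate(blocks)[:n_frames].astype(np.int16)
    return OrientationSequence(
        codes=codes, seed_id=seed_id, side=side, zcp_frames=n_frames, params=params
    )


def embed_coherent_period(
    seq: OrientationSequence,
    coherence: int,
    rng: np.random.Generator,
    signal_code: int | None = None,
) -> OrientationSequence:
    """Append a 30-frame coherent period plus 200 ms of post-CP ZCP.

    Exactly ``coherence`` CP frames (uniformly placed, not necessarily
    contiguous) carry the signal orientation and are flagged in
    ``signal_mask``.  Background CP frames continue the permutation stream
    but are resampled away from the signal orientation so the designed
    signal-frame count equals the coherence exactly.
    """
    p = seq.params
    if not 0 <= coherence <= p.cp_frames:
        raise ValueError(f"coherence must be in [0, {p.cp_frames}]")
    if signal_code is None:
        signal_code = p.signal_code(seq.side)
    cp_start = seq.zcp_frames
    total = seq.zcp_frames + p.cp_frames + p.post_cp_frames
    base = generate_orientation_sequence(
        seq.seed_id, total, p, seq.side,
        session_seed=_session_seed_of(seq),
    )
    codes = base.codes.copy()
    mask = np.zeros(total, dtype=bool)
    sig_pos = cp_start + rng.choice(p.cp_frames, size=coherence, replace=False)
    cp_slice = np.arange(cp_start, cp_start + p.cp_frames)
    bg = np.setdiff1d(cp_slice, sig_pos)
    # background CP frames must not mimic the signal by chance
    clash = bg[codes[bg] == signal_code]
    if clash.size:
        repl = rng.integers(0, p.n_orientations - 1, size=clash.size)
        repl[repl >= signal_code] += 1
        codes[clash] = repl
    codes[sig_pos] = signal_code
    mask[sig_pos] = True
    return OrientationSequence(
        codes=codes, seed_id=seq.seed_id, side=seq.side, zcp_frames=seq.zcp_frames,
        cp_start_frame=cp_start, signal_mask=mask, params=p,
    )


def _session_seed_of(seq: OrientationSequence) -> int:
    # the generating session seed is not stored on the sequence; sequences are
    # re-generated through the scheduler which passes it explicitly
    return getattr(seq, "_session_seed", 0)


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial of the change-detection task."""

    condition: str
    seed_id: int
    zcp_duration_s: float
    is_catch: bool
    change_side: str  # left | right | none
    coherence: int
    block_index: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition}")
        if self.is_catch != (self.change_side == "none"):
            raise ValueError("is_catch must coincide with change_side == none")

    @property
    def zcp_frames(self) -> int:
        return max(1, int(round(self.zcp_duration_s * 1000.0 / 10.0)))


@dataclass(frozen=True)
class ScheduleConfig:
    """Session-level schedule settings: 5 base coherences, RF side, blocks."""

    base_coherences: tuple[int, ...] = (2, 3, 4, 5, 6)
    rf_side: str = "right"
    n_blocks: int = 9
    block_counted_trials: int = 60
    params: StimulusParams = field(default_factory=StimulusParams)

    def __post_init__(self) -> None:
        if len(self.base_coherences) < 5:
            raise ValueError("need at least 5 base coherences")
        if self.rf_side not in ("left", "right"):
            raise ValueError("rf_side must be left or right")

    @property
    def away_side(self) -> str:
        return "left" if self.rf_side == "right" else "right"


class TrialScheduler:
    """Outcome-coupled trial scheduler.

    Blocks advance after ``block_counted_trials`` (default 60) hit-or-miss
    trials; conditions are randomized in sets of three so each is seen before
    any repeats.  The caller reports back, per trial, whether it counted
    (a hit or a miss) via :meth:`record_outcome`.
    """

    def __init__(self, config: ScheduleConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self._block_order: list[str] = []
        self._block_index = -1
        self._counted_in_block = 0
        self._advance_block()

    @property
    def condition(self) -> str:
        return self._block_order[self._block_index]

    @property
    def block_index(self) -> int:
        return self._block_index

    def _advance_block(self) -> None:
        self._block_index += 1
        self._counted_in_block = 0
        while len(self._block_order) <= self._block_index:
            self._block_order.extend(self.rng.permutation(list(CONDITIONS)))

    def next_trial(self) -> TrialSpec:
        cfg, rng = self.config, self.rng
        condition = self.condition
        is_catch = bool(rng.random() < cfg.params.catch_fraction)
        if is_catch:
            change_side, coherence = "none", 0
        else:
            if condition == "AI":
                change_side = cfg.rf_side
            elif condition == "AO":
                change_side = cfg.away_side
            else:
                change_side = cfg.rf_side if rng.random() < 0.5 else cfg.away_side
            coherence = int(rng.choice(cfg.base_coherences))
            if condition == "AB":
                coherence += 1  # difficulty balancing: AB coherences one frame higher
        zcp = float(sample_zcp_duration(cfg.params, rng, rate=self._zcp_rate()))
        seed_id = int(rng.integers(cfg.params.n_seeds))
        return TrialSpec(
            condition=condition, seed_id=seed_id, zcp_duration_s=zcp,
            is_catch=is_catch, change_side=change_side, coherence=coherence,
            block_index=self._block_index,
        )

    def _zcp_rate(self) -> float:
        if not hasattr(self, "_rate"):
            self._rate = calibrate_zcp_rate(self.config.params)
        return self._rate

    def record_outcome(self, counted: bool) -> None:
        """Report whether the last trial was a hit or a miss."""
        if counted:
            self._counted_in_block += 1
            if self._counted_in_block >= self.config.block_counted_trials:
                self._advance_block()

    @property
    def done(self) -> bool:
        return self._block_index >= self.config.n_blocks


def build_session_schedule(
    config: ScheduleConfig,
    rng: np.random.Generator,
    n_trials: int | None = None,
) -> list[TrialSpec]:
    """Materialize a session schedule as a flat trial list.

    Without outcomes, block advancement counts non-catch trials as hit/miss
    proxies.  If ``n_trials`` is given, exactly that many trials are emitted
    (blocks keep cycling); otherwise generation stops after
    ``config.n_blocks`` blocks.
    """
    sched = TrialScheduler(config, rng)
    trials: list[TrialSpec] = []
    while True:
        if n_trials is not None and len(trials) >= n_trials:
            break
        if n_trials is None and sched.done:
            break
        t = sched.next_trial()
        trials.append(t)
        sched.record_outcome(not t.is_catch)
    return trials


def trial_sequences(
    trial: TrialSpec,
    config: ScheduleConfig,
    rng: np.random.Generator,
    session_seed: int = 0,
    min_frames: int | None = None,
) -> dict[str, OrientationSequence]:
    """Left and right orientation sequences for a scheduled trial.

    The change side gets the coherent period embedded; the other side (and
    both sides on catch trials) continues the ZCP stream for the full trial
    duration so the two stimuli never end early.
    """
    p = config.params
    zf = trial.zcp_frames
    total = zf + p.cp_frames + p.post_cp_frames
    if min_frames is not None:
        total = max(total, min_frames)
    out: dict[str, OrientationSequence] = {}
    for side in ("left", "right"):
        seq = generate_orientation_sequence(trial.seed_id, zf, p, side, session_seed)
        seq._session_seed = session_seed  # lets embed re-generate the same stream
        if side == trial.change_side:
            seq = embed_coherent_period(seq, trial.coherence, rng)
            if seq.n_frames < total:  # pad with continued background
                full = generate_orientation_sequence(trial.seed_id, total, p, side, session_seed)
                codes = full.codes.copy()
                codes[: seq.n_frames] = seq.codes
                mask = np.zeros(total, dtype=bool)
                mask[: seq.n_frames] = seq.signal_mask
                seq = OrientationSequence(
                    codes=codes, seed_id=seq.seed_id, side=side, zcp_frames=zf,
                    cp_start_frame=seq.cp_start_frame, signal_mask=mask, params=p,
                )
        else:
            seq = generate_orientation_sequence(trial.seed_id, total, p, side, session_seed)
            seq.zcp_frames = zf
        out[side] = seq
    return out


def schedule_to_table(trials: Iterable[TrialSpec]):
    """Columnar view of a schedule (for CSV serialization)."""
    import pandas as pd

    rows = [
        dict(
            trial=i, condition=t.condition, seed_id=t.seed_id, block=t.block_index,
            zcp_ms=round(t.zcp_duration_s * 1000.0, 1), coherence=t.coherence,
            change_side=t.change_side, is_catch=t.is_catch,
        )
        for i, t in enumerate(trials)
    ]
    return pd.DataFrame(rows)
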