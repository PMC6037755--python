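"""Microsaccade detection and condition-wise statistics.

A microsaccade is an interval in which gaze displacement exceeds 0.1 degrees
over 10 ms (a 10 deg/s velocity criterion); periods of stable gaze keep the
eye within a 0.1-degree window.  Events are maximal runs of supra-threshold
10 ms displacement samples; direction is the angle of the net displacement,
binned into eight 45-degree sectors centered on the cardinal and oblique
axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MicrosaccadeEvent", "MicrosaccadeParams", "detect_microsaccades", "microsaccade_stats"]


@dataclass(frozen=True)
class MicrosaccadeParams:
    velocity_threshold_deg_per_10ms: float = 0.1
    step_ms: float = 10.0
    merge_gap_ms: float = 10.0
    dispersion_window_ms: float = 100.0  # "stable gaze" dispersion span


@dataclass
class MicrosaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude_deg: float
    direction_deg: float  # [0, 360)

    @property
    def direction_bin(self) -> int:
        """Sector 0..7; bin 0 covers [-22.5, 22.5)."""
        return int(((self.direction_deg + 22.5) % 360.0) // 45.0)


def detect_microsaccades(
    xy: np.ndarray,
    fs_hz: float = 1000.0,
    params: MicrosaccadeParams | None = None,
) -> list[MicrosaccadeEvent]:
    """Detect microsaccades in a 2-D gaze trace (degrees).

    Displacement is measured over a sliding 10 ms step; samples whose
    displacement exceeds 0.1 degrees form events, with adjacent
    supra-threshold samples (gaps up to ``merge_gap_ms``) merged.  Traces
    containing NaNs reject events spanning the gaps.  Detection is invariant
    to a global gaze offset.
    """
    params = params or MicrosaccadeParams()
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must be (n_samples, 2)")
    k = max(1, int(round(params.step_ms * fs_hz / 1000.0)))
    if len(xy) <= k:
        return []
    disp = np.linalg.norm(xy[k:] - xy[:-k], axis=1)
    valid = np.isfinite(disp)
    above = (disp > params.velocity_threshold_deg_per_10ms) & valid
    if not above.any():
        return []
    gap = max(1, int(round(params.merge_gap_ms * fs_hz / 1000.0)))
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > gap)
    runs = np.split(idx, splits + 1)
    dt_ms = 1000.0 / fs_hz
    events = []
    for run in runs:
        s, e = run[0], run[-1] + k  # event spans the displaced samples
        if not np.all(np.isfinite(xy[s:e + 1])):
            continue  # reject events spanning trace gaps
        net = xy[min(e, len(xy) - 1)] - xy[s]
        amp = float(np.linalg.norm(net))
        direc = float(np.degrees(np.arctan2(net[1], net[0])) % 360.0)
        events.append(
            MicrosaccadeEvent(
                onset_ms=s * dt_ms, offset_ms=min(e, len(xy) - 1) * dt_ms,
                amplitude_deg=amp, direction_deg=direc,
            )
        )
    return events


def microsaccade_stats(
    events_by_condition: dict[str, list[MicrosaccadeEvent]],
    analyzed_time_s: dict[str, float],
):
    """Per-condition normalized rate and 8-bin direction distribution.

    Rates (events per analyzed ZCP second) are normalized by the session
    mean rate; the direction distribution is the per-bin proportion of the
    session's total events.  Returns (normalized_rate, direction_props);
    with zero events the distribution is NaN (flagged undefined).
    """
    rates = {}
    for cond, evs in events_by_condition.items():
        t = analyzed_time_s.get(cond, 0.0)
        rates[cond] = len(evs) / t if t > 0 else float("nan")
    finite = [v for v in rates.values() if np.isfinite(v)]
    mean_rate = np.mean(finite) if finite else float("nan")
    norm = {c: (v / mean_rate if mean_rate and np.isfinite(mean_rate) and mean_rate > 0
                else float("nan")) for c, v in rates.items()}
    all_events = [e for evs in events_by_condition.values() for e in evs]
    props = np.full(8, np.nan)
    if all_events:
        bins = np.bincount([e.direction_bin for e in all_events], minlength=8)
        props = bins / bins.sum()
    return norm, props
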