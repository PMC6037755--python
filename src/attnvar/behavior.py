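"""Behavioral outcome classification, psychometric fits and summaries.

Outcomes: a saccade to the changed stimulus within the response window
(100-500 ms after CP onset, i.e. until 200 ms after the CP ends) is a hit;
no valid saccade on a change trial is a miss; maintained fixation on a catch
trial is a correct rejection; any saccade before the window opens — or to
the unchanged stimulus — is a false alarm.  Detection performance,
hits/(hits+misses) per coherence, is fit with a maximum-likelihood logistic
function and the 50% threshold extracted; confidence intervals come from a
bootstrap over trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OUTCOMES",
    "classify_outcome",
    "PsychometricFit",
    "fit_psychometric",
    "session_behavior_summary",
]

OUTCOMES = ("hit", "miss", "correct_rejection", "false_alarm")
RESPONSE_WINDOW_MS = (100.0, 500.0)  # after CP onset; CP 300 ms + 200 ms post-CP


def classify_outcome(
    is_catch: bool,
    change_side: str,
    saccade_time_ms: float | None,
    saccade_side: str | None,
    window_ms: tuple[float, float] = RESPONSE_WINDOW_MS,
) -> str:
    """Classify one completed trial.

    ``saccade_time_ms`` is relative to CP onset (negative during the ZCP);
    None means fixation was maintained.
    """
    lo, hi = window_ms
    if saccade_time_ms is None:
        return "correct_rejection" if is_catch else "miss"
    if saccade_time_ms < lo or is_catch:
        return "false_alarm"
    if saccade_time_ms > hi:
        return "miss"
    if saccade_side == change_side:
        return "hit"
    return "false_alarm"  # wrong-target saccade inside the window


@dataclass
class PsychometricFit:
    """Logistic detection function p(c) = 1/(1+exp(-(c-loc)/scale))."""

    location: float
    scale: float
    threshold_50: float
    ci_low: float
    ci_high: float
    coherences: np.ndarray
    detected_fraction: np.ndarray
    n_per_coherence: np.ndarray
    degenerate: bool = False
    extrapolated: bool = False

    def predict(self, c) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(c, dtype=float) - self.location) / self.scale))


def _logistic_mle(coh: np.ndarray, detected: np.ndarray):
    """Bernoulli ML logistic fit; returns (location, scale) with
    p = expit(b0 + b1 c), location = -b0/b1, scale = 1/b1."""
    import statsmodels.api as sm

    X = sm.add_constant(coh.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(detected.astype(float), X, family=sm.families.Binomial()).fit()
    b0, b1 = res.params
    if b1 == 0:
        return np.nan, np.nan
    return -b0 / b1, 1.0 / b1


def fit_psychometric(
    coherences: np.ndarray,
    detected: np.ndarray,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> PsychometricFit:
    """Fit detection probability vs coherence on hit/miss trials.

    ``coherences`` and ``detected`` (0/1) are per-trial.  The 50% threshold
    is the fitted location; the CI is a bootstrap percentile interval over
    trial resamples.  Complete separation (all 0s or all 1s, or a level set
    fully determined) is flagged ``degenerate``.
    """
    rng = rng or np.random.default_rng()
    coh = np.asarray(coherences, dtype=float)
    det = np.asarray(detected, dtype=float)
    levels = np.unique(coh)
    if len(levels) < 2:
        raise ValueError("need >= 2 coherence levels")
    frac = np.array([det[coh == c].mean() for c in levels])
    n_per = np.array([(coh == c).sum() for c in levels])
    degenerate = bool(det.min() == det.max())
    if degenerate:
        return PsychometricFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               levels, frac, n_per, degenerate=True)
    loc, scale = _logistic_mle(coh, det)
    boots = []
    n = len(coh)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        if det[idx].min() == det[idx].max():
            continue
        b_loc, _ = _logistic_mle(coh[idx], det[idx])
        if np.isfinite(b_loc):
            boots.append(b_loc)
    if boots:
        a = (1 - ci) / 2
        ci_low, ci_high = np.quantile(boots, [a, 1 - a])
    else:
        ci_low = ci_high = np.nan
    extrapolated = not (levels.min() <= loc <= levels.max())
    return PsychometricFit(
        location=float(loc), scale=float(scale), threshold_50=float(loc),
        ci_low=float(ci_low), ci_high=float(ci_high),
        coherences=levels, detected_fraction=frac, n_per_coherence=n_per,
        degenerate=False, extrapolated=extrapolated,
    )


def session_behavior_summary(outcomes: list[str], reaction_times: list[float | None]):
    """Detection %, false-alarm rate and reaction-time summary.

    detection = hits/(hits+misses); FA rate uses all valid trials
    (hits+misses+CRs+FAs); RT summary is the median and the median absolute
    deviation over hit trials.  Returns a dict; rates are fractions.
    """
    counts = {o: 0 for o in OUTCOMES}
    for o in outcomes:
        if o not in counts:
            raise ValueError(f"unknown outcome {o}")
        counts[o] += 1
    hm = counts["hit"] + counts["miss"]
    total = sum(counts.values())
    rts = np.array([rt for o, rt in zip(outcomes, reaction_times)
                    if o == "hit" and rt is not None], dtype=float)
    return dict(
        n=total,
        n_hit=counts["hit"], n_miss=counts["miss"],
        n_correct_rejection=counts["correct_rejection"], n_false_alarm=counts["false_alarm"],
        detected_fraction=counts["hit"] / hm if hm else float("nan"),
        false_alarm_rate=counts["false_alarm"] / total if total else float("nan"),
        median_rt_ms=float(np.median(rts)) if rts.size else float("nan"),
        mad_rt_ms=float(np.median(np.abs(rts - np.median(rts)))) if rts.size else float("nan"),
    )
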