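"""Von Mises tuning fits with condition-specific gain and offset.

The tuning curve is modeled as Y = w1 + exp(w2 + w3*cos(x - w4)) where x is
the doubled orientation angle in radians (so the 180-degree orientation
circle maps onto one von Mises period), w1 is an additive offset, exp(w2) a
multiplicative gain, w3 the concentration and w4 the preferred orientation.
Shape (w3) and preference (w4) are assumed not to change with attention;
per-condition responses are then regressed on the fixed tuning basis
theta_i = exp(w3*cos(x_i - w4)) with a condition indicator and interaction,

    y_i = b0 + b1*theta_i + b2*X2 + b3*theta_i*X2,

so b2 captures an offset change and b3 a gain change between conditions.
An F-test of the full model against the reduced (b0, b1) model flags
attentional modulation; coefficient t-tests then classify it as gain,
offset or mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

__all__ = ["VonMisesFit", "ConditionModulationFit", "fit_von_mises", "fit_condition_modulation"]


@dataclass
class VonMisesFit:
    w1: float  # offset (spikes/bin)
    w2: float  # log-gain
    w3: float  # concentration
    w4: float  # preferred orientation, radians on the doubled-angle circle
    residual_variance: float
    converged: bool

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.w1 + np.exp(self.w2 + self.w3 * np.cos(np.asarray(x) - self.w4))

    @property
    def preferred_orientation_deg(self) -> float:
        return float(np.rad2deg(self.w4 % (2 * np.pi)) / 2.0)


@dataclass
class ConditionModulationFit:
    betas: np.ndarray  # b0..b3
    se: np.ndarray
    f_stat: float
    f_p: float
    t_offset: float
    p_offset: float
    t_gain: float
    p_gain: float
    classification: str  # none | gain | offset | mixed


def _doubled_angles(n: int = 36) -> np.ndarray:
    return np.deg2rad(2.0 * np.arange(n) * 5.0)


def fit_von_mises(
    responses: np.ndarray,
    x: np.ndarray | None = None,
    n_starts: int = 8,
    tol: float = 1e-8,
) -> VonMisesFit:
    """Nonlinear least squares fit of the four-parameter von Mises curve.

    Multi-start over a grid of ``n_starts`` preferred orientations with
    Levenberg-Marquardt-style refinement (scipy ``least_squares``); the best
    solution is returned.  A flat curve yields w3 -> 0 with ``converged``
    False (w4 unidentifiable).
    """
    y = np.asarray(responses, dtype=float)
    if x is None:
        x = _doubled_angles(len(y))
    if len(y) != len(x):
        raise ValueError("responses and angles differ in length")
    span = y.max() - y.min()
    if span <= 0 or not np.isfinite(span):
        return VonMisesFit(float(y.mean()), -np.inf, 0.0, 0.0, 0.0, False)

    def resid(p):
        w1, w2, w3, w4 = p
        return w1 + np.exp(w2 + w3 * np.cos(x - w4)) - y

    best = None
    w1_0 = float(y.min())
    w2_0 = float(np.log(max(span, 1e-9)) - 1.0)
    for w4_0 in np.linspace(0, 2 * np.pi, n_starts, endpoint=False):
        try:
            sol = least_squares(
                resid,
                x0=[w1_0, w2_0, 1.0, w4_0],
                # w3 capped: beyond ~20 the curve is a delta on the 36-point
                # grid and exp() overflows in the condition regression
                bounds=([-np.inf, -50.0, 0.0, -np.inf], [np.inf, 50.0, 20.0, np.inf]),
                xtol=tol, ftol=tol, gtol=tol,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VonMisesFit(float(y.mean()), -np.inf, 0.0, 0.0, float(y.var()), False)
    w1, w2, w3, w4 = best.x
    w4 = float(w4 % (2 * np.pi))
    dof = max(len(y) - 4, 1)
    rv = float(2 * best.cost / dof)
    return VonMisesFit(float(w1), float(w2), float(w3), w4, rv, bool(best.success))


def fit_condition_modulation(
    responses_ref: np.ndarray,
    responses_cmp: np.ndarray,
    base: VonMisesFit,
    x: np.ndarray | None = None,
    weights_ref: np.ndarray | None = None,
    weights_cmp: np.ndarray | None = None,
    alpha: float = 0.05,
) -> ConditionModulationFit:
    """Condition regression on the shared tuning basis.

    ``responses_ref``/``responses_cmp`` are per-orientation mean responses in
    the reference (X2 = 0) and comparison (X2 = 1) conditions, optionally
    weighted by trial counts.  The omnibus F-test compares the full model
    (b0..b3) to the reduced (b0, b1) model; when significant, t-tests on b2
    (offset) and b3 (gain) classify the modulation.
    """
    if not np.isfinite(base.w2):
        raise ValueError("base von Mises fit did not converge")
    y0 = np.asarray(responses_ref, dtype=float)
    y1 = np.asarray(responses_cmp, dtype=float)
    if x is None:
        x = _doubled_angles(len(y0))
    theta = np.exp(base.w3 * np.cos(x - base.w4))
    y = np.r_[y0, y1]
    cond = np.r_[np.zeros(len(y0)), np.ones(len(y1))]
    th = np.r_[theta, theta]
    X_full = np.column_stack([np.ones_like(y), th, cond, th * cond])
    X_red = X_full[:, :2]
    w = np.ones_like(y)
    if weights_ref is not None:
        w[: len(y0)] = weights_ref
    if weights_cmp is not None:
        w[len(y0):] = weights_cmp
    sw = np.sqrt(w)
    beta, rss_full = _wls(X_full, y, sw)
    _, rss_red = _wls(X_red, y, sw)
    n, k_full = len(y), X_full.shape[1]
    df2 = n - k_full
    df1 = k_full - X_red.shape[1]
    if df2 <= 0:
        raise ValueError("not enough orientations for the condition regression")
    num = max(rss_red - rss_full, 0.0)
    scale = float(y @ y) + 1.0
    if rss_full <= 1e-12 * scale:  # (near-)perfect full fit
        f = 0.0 if num <= 1e-12 * scale else np.inf
    else:
        f = (num / df1) / (rss_full / df2)
    f_p = float(stats.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    # coefficient SEs from the weighted normal matrix
    s2 = rss_full / df2
    Xw = X_full * sw[:, None]
    cov = s2 * np.linalg.pinv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_off = beta[2] / se[2] if se[2] > 0 else np.inf * np.sign(beta[2])
        t_gain = beta[3] / se[3] if se[3] > 0 else np.inf * np.sign(beta[3])
    p_off = float(2 * stats.t.sf(abs(t_off), df2))
    p_gain = float(2 * stats.t.sf(abs(t_gain), df2))
    if f_p >= alpha:
        cls = "none"
    else:
        sig_off, sig_gain = p_off < alpha, p_gain < alpha
        cls = {(True, True): "mixed", (True, False): "offset",
               (False, True): "gain", (False, False): "none"}[(sig_off, sig_gain)]
    return ConditionModulationFit(
        betas=beta, se=se, f_stat=float(f), f_p=f_p,
        t_offset=float(t_off), p_offset=p_off,
        t_gain=float(t_gain), p_gain=p_gain,
        classification=cls,
    )


def _wls(X: np.ndarray, y: np.ndarray, sqrt_w: np.ndarray):
    Xw = X * sqrt_w[:, None]
    yw = y * sqrt_w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    return beta, float(r @ r)
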