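"""Block-wise z-scored spike-count correlations and Fano factors.

Spike-count correlations (r_sc) are Pearson correlations of two units'
z-scored counts over repeated presentations of identical stimulus sequences
(same random seed).  Z-scoring and Fano factors are computed block-wise —
within cells of (unit, seed, attention block) — so that slow drifts in
excitability across a session do not masquerade as trial-to-trial
covariability.  Cells need at least 3 trials and nonzero variance; sparse
cells fall back to session-wide per-seed statistics.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "blockwise_zscore",
    "spike_count_correlation",
    "pairwise_rsc_matrix",
    "fano_factor",
    "correlation_contrast",
    "eccentricity_trend",
]

MIN_TRIALS_PER_CELL = 3


def _cells(seed: np.ndarray, block: np.ndarray | None):
    if block is None:
        keys = seed.astype(np.int64)
    else:
        keys = seed.astype(np.int64) * 100000 + block.astype(np.int64)
    return keys


def blockwise_zscore(
    counts: np.ndarray,
    seed: np.ndarray,
    block: np.ndarray | None = None,
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> np.ndarray:
    """Z-score counts within (seed, block) cells.

    ``counts`` is (n_units, n_trials) or (n_trials,).  Cells with fewer than
    ``min_trials`` trials fall back to pooled per-seed statistics; cells (or
    fallback groups) with zero variance are returned as NaN (dropped
    downstream).  Uses the unbiased (n-1) standard deviation.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n_units, n_trials = counts.shape
    seed = np.asarray(seed)
    if len(seed) != n_trials:
        raise ValueError("seed labels must match trial count")
    z = np.full_like(counts, np.nan)
    keys = _cells(seed, block)
    seed_keys = _cells(seed, None)
    for u in range(n_units):
        for key in np.unique(keys):
            idx = np.flatnonzero(keys == key)
            if len(idx) < min_trials:
                # fall back to the per-seed group
                sk = seed_keys[idx[0]]
                idx_pool = np.flatnonzero(seed_keys == sk)
                if len(idx_pool) < min_trials:
                    continue
                mu, sd = counts[u, idx_pool].mean(), counts[u, idx_pool].std(ddof=1)
            else:
                mu, sd = counts[u, idx].mean(), counts[u, idx].std(ddof=1)
            if sd > 0:
                z[u, idx] = (counts[u, idx] - mu) / sd
    if np.all(np.isnan(z)):
        raise ValueError("all z-scoring cells degenerate")
    return z if z.shape[0] > 1 else z[0]


def spike_count_correlation(z_a: np.ndarray, z_b: np.ndarray, min_pairs: int = 3) -> float:
    """Pearson correlation of two aligned z-score vectors (NaNs dropped
    pairwise); NaN when fewer than ``min_pairs`` joint observations."""
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    ok = np.isfinite(z_a) & np.isfinite(z_b)
    if ok.sum() < min_pairs:
        return float("nan")
    a, b = z_a[ok], z_b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pairwise_rsc_matrix(z: np.ndarray) -> np.ndarray:
    """All-pairs r_sc from a (n_units, n_trials) z-score matrix (NaN-aware);
    the diagonal is NaN."""
    n = z.shape[0]
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = spike_count_correlation(z[i], z[j])
    return out


def fano_factor(
    counts: np.ndarray,
    seed: np.ndarray,
    block: np.ndarray | None = None,
    min_trials: int = MIN_TRIALS_PER_CELL,
) -> float:
    """Block-wise Fano factor: variance/mean per (seed, block) cell,
    combined across cells weighted by trial count.  Zero-mean cells are
    dropped; NaN if no cell qualifies."""
    counts = np.asarray(counts, dtype=float)
    keys = _cells(np.asarray(seed), block)
    num = den = 0.0
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        if len(idx) < min_trials:
            continue
        mu = counts[idx].mean()
        if mu <= 0:
            continue
        f = counts[idx].var(ddof=1) / mu
        num += f * len(idx)
        den += len(idx)
    return num / den if den else float("nan")


def correlation_contrast(r_ai: float, r_ab: float, r_ao: float) -> float:
    """AB elevation of correlations: r_AB - (r_AI + r_AO)/2; NaN unless all
    three condition means exist."""
    vals = np.array([r_ai, r_ab, r_ao], dtype=float)
    if not np.all(np.isfinite(vals)):
        return float("nan")
    return float(r_ab - 0.5 * (r_ai + r_ao))


def eccentricity_trend(contrasts: np.ndarray, eccentricities: np.ndarray):
    """Pearson correlation of the session correlation contrast with stimulus
    horizontal eccentricity; returns (r, t, p) with t = r*sqrt((n-2)/(1-r^2))
    and a two-tailed p."""
    c = np.asarray(contrasts, dtype=float)
    e = np.asarray(eccentricities, dtype=float)
    ok = np.isfinite(c) & np.isfinite(e)
    c, e = c[ok], e[ok]
    n = len(c)
    if n < 3:
        raise ValueError("need at least 3 sessions")
    if e.std() == 0:
        raise ValueError("eccentricities are constant; trend undefined")
    r = float(np.corrcoef(c, e)[0, 1])
    if abs(r) >= 1.0:
        return r, float("inf") * np.sign(r), 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return r, float(t), p
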