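"""Shift-corrected cross-correlograms and the cumulative correlation
coefficient r_CCG.

For a pair of units j, k the raw cross-correlogram counts spike
coincidences per 1 ms lag, averaged over trials.  The shift predictor — the
cross-correlation of the two units' trial-averaged spike density functions,
computed per stimulus seed since different seeds show different stimuli —
captures the stimulus-locked component and is subtracted, leaving the
shift-corrected correlogram C_jk(tau).  Its cumulative integral
A_jk(tau) = sum_{|t| <= tau} C_jk(t), normalized as

    r_CCG(tau) = A_jk(tau) / sqrt(A_jj(T) * A_kk(T)),   T = 1000 ms,

measures correlation as a function of timescale.  Because the zero-lag bin
of the auto-correlogram retains the spike-count term, A_jj(T) is exactly the
(biased, per-seed-centered) spike-count variance over the window, so
r_CCG(T) coincides with the Pearson spike-count correlation over the same
trials — the identity used to validate the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CorrelogramResult", "correlogram_set", "cross_correlogram", "cumulative_r_ccg"]


@dataclass
class CorrelogramResult:
    """All-pairs corrected correlograms for one condition.

    ``corrected`` has shape (U, U, 2T-1), lag axis from -(T-1) to T-1 ms;
    entry [j, k, :] is the per-trial average of coincidence sums (raw minus
    shift predictor).  ``ccg_normalized`` divides by the triangular overlap
    (T - |tau|); the same factor would apply to raw and predictor alike, so
    the correction itself is unaffected by this choice.
    """

    corrected: np.ndarray
    lags_ms: np.ndarray
    n_trials: int
    window_ms: int

    def ccg_normalized(self, j: int, k: int) -> np.ndarray:
        tri = self.window_ms - np.abs(self.lags_ms)
        return self.corrected[j, k] / tri

    def pair(self, j: int, k: int) -> np.ndarray:
        return self.corrected[j, k]


def correlogram_set(
    trial_matrices: list[np.ndarray],
    seeds: np.ndarray | list[int],
    window_ms: int = 1000,
) -> CorrelogramResult:
    """Corrected auto-/cross-correlograms for all unit pairs.

    ``trial_matrices`` holds one (n_units, window_ms) binned spike matrix
    (1 ms bins, first ``window_ms`` of the ZCP) per trial; ``seeds`` labels
    each trial's stimulus seed.  The shift predictor is built from the
    trial-averaged PSTH within each seed.
    """
    if not trial_matrices:
        raise ValueError("no trials")
    T = window_ms
    U = trial_matrices[0].shape[0]
    seeds = np.asarray(seeds)
    if len(seeds) != len(trial_matrices):
        raise ValueError("seed labels must match trials")
    totals = np.zeros(U)
    for m in trial_matrices:
        totals += m.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("a unit has no spikes in the analysis window")
    nfft = 1
    while nfft < 2 * T:
        nfft *= 2
    nf = nfft // 2 + 1
    spec = np.zeros((U, U, nf), dtype=complex)
    n_total = 0
    for s in np.unique(seeds):
        idx = np.flatnonzero(seeds == s)
        n_s = len(idx)
        psth = np.zeros((U, T))
        for i in idx:
            x = trial_matrices[i].astype(float)
            F = np.fft.rfft(x, n=nfft, axis=1)
            spec += np.conj(F)[:, None, :] * F[None, :, :]
            psth += x
        psth /= n_s
        Fm = np.fft.rfft(psth, n=nfft, axis=1)
        spec -= n_s * np.conj(Fm)[:, None, :] * Fm[None, :, :]
        n_total += n_s
    c = np.fft.irfft(spec, n=nfft, axis=2) / n_total
    # lag m in irfft index m (positive), nfft - m (negative)
    lags = np.arange(-(T - 1), T)
    corrected = np.concatenate([c[:, :, nfft - (T - 1):], c[:, :, :T]], axis=2)
    return CorrelogramResult(
        corrected=corrected, lags_ms=lags, n_trials=n_total, window_ms=T
    )


def cross_correlogram(
    spikes_a: list[np.ndarray],
    spikes_b: list[np.ndarray],
    seeds: np.ndarray | list[int],
    window_ms: int = 1000,
) -> CorrelogramResult:
    """Pairwise convenience wrapper: per-trial spike-time lists (ms) for two
    units; bins at 1 ms and delegates to :func:`correlogram_set`."""
    mats = []
    for a, b in zip(spikes_a, spikes_b):
        m = np.zeros((2, window_ms))
        for row, times in enumerate((a, b)):
            t = np.asarray(times)
            t = t[(t >= 0) & (t < window_ms)].astype(int)
            np.add.at(m[row], t, 1.0)
        mats.append(m)
    return correlogram_set(mats, seeds, window_ms)


def cumulative_r_ccg(
    result: CorrelogramResult,
    j: int,
    k: int,
    tau_grid: np.ndarray | None = None,
):
    """r_CCG(tau) curve for one pair.

    Returns (tau_grid, r_ccg).  NaN (flagged undefined) when either
    auto-correlogram integral at T is non-positive.
    """
    T = result.window_ms
    if tau_grid is None:
        tau_grid = np.arange(1, T + 1)
    lags = result.lags_ms

    def integral(c, tau):
        return c[np.abs(lags) <= tau].sum()

    a_jj = integral(result.corrected[j, j], T)
    a_kk = integral(result.corrected[k, k], T)
    if a_jj <= 0 or a_kk <= 0:
        return tau_grid, np.full(len(tau_grid), np.nan)
    denom = np.sqrt(a_jj * a_kk)
    c_jk = result.corrected[j, k]
    order = np.abs(lags)
    # cumulative over |lag| <= tau via sorted prefix sums
    sort_idx = np.argsort(order, kind="stable")
    sorted_abs = order[sort_idx]
    csum = np.cumsum(c_jk[sort_idx])
    pos = np.searchsorted(sorted_abs, tau_grid, side="right") - 1
    a_tau = np.where(pos >= 0, csum[np.clip(pos, 0, None)], 0.0)
    return tau_grid, a_tau / denom
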