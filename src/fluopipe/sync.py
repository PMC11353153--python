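"""Network synchrony: phase-locking values and sliding-window cross-correlation.

Phase locking between two cells is measured as
PLV = |mean_t exp(i (phi_a(t) - phi_b(t)))| with instantaneous phases from
a zero-phase band-pass filter followed by the analytic signal. PLV is 1
for a constant phase relationship and ~1/sqrt(N) for independent phases
(Rayleigh). Samples within ``edge_zero_s`` of either end are excluded from
the mean — filter and Hilbert transients there would otherwise bias the
estimate.

Sliding-window cross-correlation reports, per window and cell pair, the
maximum Pearson correlation over integer-sample lags and the lag attaining
it, giving a time-resolved picture of who leads whom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .spectral import BandDefinition

__all__ = [
    "PLVMatrix",
    "XCorrResult",
    "instantaneous_phase",
    "plv",
    "plv_matrix",
    "sliding_xcorr",
    "xcorr_matrices",
    "autocorr",
]


@dataclass
class PLVMatrix:
    values: np.ndarray  # symmetric [cell, cell] in [0, 1]
    band: BandDefinition
    edge_zero_s: float
    n_samples_used: int
    cell_ids: list


@dataclass
class XCorrResult:
    max_corr: np.ndarray  # [window, cell, cell]
    lag_at_max: np.ndarray  # [window, cell, cell], seconds
    window_times: np.ndarray  # window centres, seconds
    window_size_s: float
    step_s: float
    max_lag_s: float
    cell_ids: list


def instantaneous_phase(trace, sampling_rate: float, band: BandDefinition,
                        order: int = 4) -> np.ndarray:
    """Band-limited instantaneous phase in (-pi, pi].

    Butterworth band-pass of the given order applied forward-backward
    (zero phase), then the analytic-signal angle.
    """
    x = np.asarray(trace, dtype=np.float64)
    nyq = sampling_rate / 2.0
    if band.f_high >= nyq:
        raise ValueError(f"band upper edge {band.f_high} Hz at or above Nyquist ({nyq} Hz)")
    sos = butter(order, [band.f_low, band.f_high], btype="bandpass",
                 fs=sampling_rate, output="sos")
    # sosfiltfilt needs ~3 filter lengths of data for its edge padding
    if len(x) <= 6 * (2 * order + 1):
        raise ValueError(f"trace of {len(x)} samples too short for the band-pass filter")
    filtered = sosfiltfilt(sos, x)
    return np.angle(hilbert(filtered))


def plv(phases_a, phases_b, edge_zero_s: float = 0.0, sampling_rate: float = 1.0) -> float:
    """Phase-locking value of two phase series, edges excluded.

    Samples within ``edge_zero_s`` of either end are dropped from the
    circular mean (excluding rather than literally zeroing them, which
    would bias the estimate toward zero phase difference).
    """
    pa = np.asarray(phases_a, dtype=np.float64)
    pb = np.asarray(phases_b, dtype=np.float64)
    if pa.shape != pb.shape:
        raise ValueError("phase series must have equal length")
    n_edge = int(round(edge_zero_s * sampling_rate))
    if 2 * n_edge >= len(pa):
        raise ValueError("edge exclusion removes every sample")
    sl = slice(n_edge, len(pa) - n_edge) if n_edge else slice(None)
    return float(np.abs(np.mean(np.exp(1j * (pa[sl] - pb[sl])))))


def plv_matrix(traceset, band: BandDefinition, edge_zero_s: float | None = None) -> PLVMatrix:
    """Pairwise PLV over every cell pair of a trace set, in one band.

    Default edge exclusion is two periods of the band's lower edge.
    """
    if traceset.dff is None:
        raise ValueError("traces have no dF/F0; run compute_dff first")
    fs = traceset.sampling_rate
    if edge_zero_s is None:
        edge_zero_s = 2.0 / band.f_low
    K = traceset.dff.shape[1]
    phases = [instantaneous_phase(np.nan_to_num(traceset.dff[:, k]), fs, band)
              for k in range(K)]
    values = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            v = plv(phases[a], phases[b], edge_zero_s, fs)
            values[a, b] = values[b, a] = v
    n_edge = int(round(edge_zero_s * fs))
    return PLVMatrix(values=values, band=band, edge_zero_s=edge_zero_s,
                     n_samples_used=traceset.dff.shape[0] - 2 * n_edge,
                     cell_ids=list(traceset.roi_ids))


def _lag_order(max_lag: int) -> list:
    """Lags in tie-break order: smallest |lag| first, negative before positive."""
    order = [0]
    for m in range(1, max_lag + 1):
        order.extend([-m, m])
    return order


def _window_xcorr(aw: np.ndarray, bw: np.ndarray, max_lag: int, exclude_zero=False):
    """Max Pearson correlation over integer lags within one window.

    lag > 0 means b trails a by that many samples. Returns (corr, lag) or
    (nan, 0) when either overlap segment has zero variance at every lag.
    """
    best = -np.inf
    best_lag = 0
    found = False
    for lag in _lag_order(max_lag):
        if exclude_zero and lag == 0:
            continue
        if lag >= 0:
            x, y = aw[: len(aw) - lag], bw[lag:]
        else:
            x, y = aw[-lag:], bw[: len(bw) + lag]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
        # strict improvement beyond rounding noise, so exact ties (e.g.
        # lags one period apart on a sinusoid) resolve to the smallest
        # |lag|, negative first
        if r > best + 1e-12:
            best, best_lag, found = r, lag, True
    if not found:
        return np.nan, 0
    return best, best_lag


def sliding_xcorr(trace_a, trace_b, sampling_rate: float,
                  window_size_s: float | None = None, step_s: float | None = None,
                  max_lag_s: float | None = None, exclude_zero_lag: bool = False):
    """Time-resolved cross-correlation of two traces.

    Defaults derive from the sampling interval: window 256 samples, step 64
    samples, max lag a quarter window. Returns
    ``(window_centres_s, max_corr, lag_s)`` arrays, one entry per window;
    windows where either trace is constant yield NaN correlation.
    """
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    W = int(round(window_size_s * sampling_rate)) if window_size_s else 256
    step = int(round(step_s * sampling_rate)) if step_s else 64
    L = int(round(max_lag_s * sampling_rate)) if max_lag_s else W // 4
    if W > n:
        raise ValueError(f"window of {W} samples longer than trace ({n})")
    if W < 4 * L:
        raise ValueError("window must be at least 4x the maximum lag")
    starts = np.arange(0, n - W + 1, step)
    centres = (starts + W / 2) / sampling_rate
    corr = np.empty(len(starts))
    lag = np.empty(len(starts))
    for i, s0 in enumerate(starts):
        c, l = _window_xcorr(a[s0:s0 + W], b[s0:s0 + W], L, exclude_zero=exclude_zero_lag)
        corr[i] = c
        lag[i] = l / sampling_rate
    return centres, corr, lag


def xcorr_matrices(traceset, window_size_s: float | None = None,
                   step_s: float | None = None, max_lag_s: float | None = None) -> XCorrResult:
    """Sliding-window max correlation and lag for every cell pair.

    ``max_corr`` is symmetric per window and ``lag_at_max`` antisymmetric
    (lag[a, b] = -lag[b, a]); the diagonal is correlation 1 at lag 0.
    """
    if traceset.dff is None:
        raise ValueError("traces have no dF/F0; run compute_dff first")
    fs = traceset.sampling_rate
    K = traceset.dff.shape[1]
    probe = sliding_xcorr(traceset.dff[:, 0] if K else np.zeros(512),
                          traceset.dff[:, 0] if K else np.zeros(512),
                          fs, window_size_s, step_s, max_lag_s)
    n_win = len(probe[0])
    W_s = window_size_s if window_size_s else 256 / fs
    step_eff = step_s if step_s else 64 / fs
    max_lag_eff = max_lag_s if max_lag_s else (256 // 4) / fs
    max_corr = np.ones((n_win, K, K))
    lag = np.zeros((n_win, K, K))
    for a in range(K):
        for b in range(a + 1, K):
            _, c, l = sliding_xcorr(np.nan_to_num(traceset.dff[:, a]),
                                    np.nan_to_num(traceset.dff[:, b]),
                                    fs, window_size_s, step_s, max_lag_s)
            max_corr[:, a, b] = max_corr[:, b, a] = c
            lag[:, a, b] = l
            lag[:, b, a] = -l
    return XCorrResult(max_corr=max_corr, lag_at_max=lag, window_times=probe[0],
                       window_size_s=W_s, step_s=step_eff, max_lag_s=max_lag_eff,
                       cell_ids=list(traceset.roi_ids))


def autocorr(trace, sampling_rate: float, window_size_s: float | None = None,
             step_s: float | None = None, max_lag_s: float | None = None):
    """Sliding-window autocorrelation (zero lag excluded from the argmax)."""
    return sliding_xcorr(trace, trace, sampling_rate, window_size_s, step_s,
                         max_lag_s, exclude_zero_lag=True)
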