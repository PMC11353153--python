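"""Continuous wavelet analysis with a complex Morlet wavelet.

The transform convolves the signal with scaled copies of the analytic
Morlet wavelet psi(t) = pi^(-1/4) exp(i w0 t) exp(-t^2/2), w0 = 6, on a
log-spaced frequency grid. Scales map to frequency through
f = w0 / (2 pi s), which puts the across-scale response maximum of a pure
tone exactly at the tone frequency. Coefficients are L1-normalised per
scale (the 1/s convention) and calibrated so a unit-amplitude sinusoid
yields a ridge magnitude of ~1 at every frequency, making band powers
comparable across the grid.

Band summaries use the conventional physiological ranges — delta 0.5–4,
theta 4–8, alpha 8–13, beta 13–30 Hz — as half-open intervals [low, high)
so the four bands tile 0.5–30 Hz without double counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "OMEGA0",
    "BandDefinition",
    "DEFAULT_BANDS",
    "WaveletResult",
    "SessionSpectra",
    "cwt_morlet",
    "band_power",
    "analyze_session",
]

#: Morlet centre-frequency parameter (time-frequency trade-off)
OMEGA0 = 6.0

# peak of the Fourier transform of the analytic Morlet at its centre
# frequency; used to calibrate ridge magnitude to signal amplitude
_PSI_HAT_PEAK = np.pi ** (-0.25) * np.sqrt(2.0 * np.pi)
_AMPLITUDE_CAL = 2.0 / _PSI_HAT_PEAK


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f_low, f_high) in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError(f"invalid band {self.name}: ({self.f_low}, {self.f_high})")


DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)


@dataclass
class WaveletResult:
    """Complex CWT coefficients over (frequency, time)."""

    coefficients: np.ndarray
    frequencies: np.ndarray
    sampling_rate: float
    normalization: str = "l1-amplitude"
    source: str = ""
    coi: np.ndarray | None = None  # True where the cone of influence is clean

    def __post_init__(self):
        if self.coefficients.shape[0] != len(self.frequencies):
            raise ValueError("coefficient rows must match the frequency grid")
        f = np.asarray(self.frequencies)
        if np.any(np.diff(f) <= 0) or f[-1] >= self.sampling_rate / 2:
            raise ValueError("frequencies must increase and stay below Nyquist")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.coefficients.shape[1]) / self.sampling_rate


def _scales_for(frequencies: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Scale in samples for each requested frequency (f = w0 / 2 pi s)."""
    return OMEGA0 * sampling_rate / (2.0 * np.pi * frequencies)


def cwt_morlet(signal, sampling_rate: float, f_min: float = 0.5, f_max: float = 30.0,
               n_freqs: int = 64, source: str = "") -> WaveletResult:
    """Complex Morlet CWT on a log-spaced frequency grid.

    Parameters
    ----------
    signal : 1-D time series (no NaNs; interpolate beforehand).
    sampling_rate : Hz.
    f_min, f_max : grid limits in Hz; ``f_max`` must be below Nyquist.
    n_freqs : number of log-spaced grid points (voices).

    Returns a :class:`WaveletResult` whose ``coi`` mask is False within one
    e-folding time (sqrt(2)·s) of either edge.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if np.any(~np.isfinite(x)):
        raise ValueError("signal contains NaN/inf; interpolate before the CWT")
    nyq = sampling_rate / 2.0
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    if f_max >= nyq:
        raise ValueError(f"f_max {f_max} Hz must be below Nyquist ({nyq} Hz)")
    if len(x) < 2 * sampling_rate / f_min:
        warnings.warn("signal shorter than two periods of f_min: edge-dominated transform")

    freqs = np.geomspace(f_min, f_max, n_freqs)
    scales = _scales_for(freqs, sampling_rate)
    # remove the DC offset: the wavelet is zero-mean, so this leaves every
    # oscillatory component untouched while killing the step response the
    # truncated kernels would otherwise see at the signal edges
    x = x - x.mean()
    n = len(x)
    coefs = np.empty((n_freqs, n), dtype=np.complex128)
    coi = np.zeros((n_freqs, n), dtype=bool)
    t_idx = np.arange(n)
    for j, s in enumerate(scales):
        half = int(np.ceil(5.0 * s))
        u = np.arange(-half, half + 1) / s
        psi = np.pi ** (-0.25) * np.exp(1j * OMEGA0 * u) * np.exp(-0.5 * u * u)
        # cross-correlation with the scaled wavelet, L1 normalisation (1/s)
        kernel = np.conj(psi)[::-1] / s
        coefs[j] = fftconvolve(x, kernel, mode="same") * _AMPLITUDE_CAL
        efold = np.sqrt(2.0) * s
        coi[j] = (t_idx >= efold) & (t_idx <= n - 1 - efold)
    return WaveletResult(coefficients=coefs, frequencies=freqs,
                         sampling_rate=sampling_rate, source=source, coi=coi)


def band_power(wavelet: WaveletResult, band: BandDefinition) -> np.ndarray:
    """Sum of coefficient magnitudes over grid frequencies in [low, high).

    Half-open intervals mean the default delta/theta/alpha/beta set tiles
    the grid without any frequency contributing to two bands.
    """
    f = wavelet.frequencies
    sel = (f >= band.f_low) & (f < band.f_high)
    if not sel.any():
        raise ValueError(f"band {band.name} [{band.f_low}, {band.f_high}) Hz "
                         "overlaps no grid frequency")
    return wavelet.magnitude[sel].sum(axis=0)


@dataclass
class SessionSpectra:
    """Band powers for every cell (cell time base) and the ephys trace."""

    bands: tuple
    cell_ids: list
    cell_band_power: np.ndarray  # [cell, band, time]
    cell_times: np.ndarray
    cell_wavelets: list = field(default_factory=list)
    ephys_band_power: np.ndarray | None = None  # [band, time]
    ephys_times: np.ndarray | None = None
    ephys_wavelet: WaveletResult | None = None


def analyze_session(traceset, ephys=None, bands=DEFAULT_BANDS,
                    f_min: float = 0.5, f_max: float = 30.0, n_freqs: int = 64,
                    keep_wavelets: bool = False) -> SessionSpectra:
    """Wavelet-decompose every cell trace and the ephys on one band set.

    Cells are analysed at the imaging rate and the ephys at its own rate;
    both time axes share t = 0 so band-power panels overlay directly. When
    the imaging rate cannot support ``f_max`` the grid is clipped below
    Nyquist with a warning.
    """
    if traceset.dff is None:
        raise ValueError("traces have no dF/F0; run compute_dff first")
    fs_cell = traceset.sampling_rate
    fmax_cell = min(f_max, 0.95 * fs_cell / 2)
    if fmax_cell < f_max:
        warnings.warn(f"imaging rate {fs_cell:.3g} Hz cannot resolve {f_max} Hz; "
                      f"grid clipped at {fmax_cell:.3g} Hz")
    n_cells = traceset.dff.shape[1]
    if n_cells == 0:
        warnings.warn("no valid cells to analyse")

    def bands_or_nan(w):
        # bands falling entirely above a clipped grid yield NaN rows
        out = []
        for b in bands:
            sel = (w.frequencies >= b.f_low) & (w.frequencies < b.f_high)
            out.append(band_power(w, b) if sel.any()
                       else np.full(w.coefficients.shape[1], np.nan))
        return np.stack(out)

    powers = []
    wavelets = []
    for k in range(n_cells):
        w = cwt_morlet(np.nan_to_num(traceset.dff[:, k]), fs_cell, f_min, fmax_cell,
                       n_freqs, source=f"cell {traceset.roi_ids[k]}")
        powers.append(bands_or_nan(w))
        if keep_wavelets:
            wavelets.append(w)
    cell_bp = (np.stack(powers) if powers
               else np.zeros((0, len(bands), traceset.F.shape[0])))

    ephys_bp = ephys_times = ephys_w = None
    if ephys is not None:
        fmax_e = min(f_max, 0.95 * ephys.sampling_rate / 2)
        ephys_w = cwt_morlet(ephys.samples, ephys.sampling_rate, f_min, fmax_e,
                             n_freqs, source="ephys")
        ephys_bp = bands_or_nan(ephys_w)
        ephys_times = ephys.t0_offset + ephys_w.times
    return SessionSpectra(
        bands=tuple(bands), cell_ids=list(traceset.roi_ids),
        cell_band_power=cell_bp, cell_times=np.asarray(traceset.time_axis),
        cell_wavelets=wavelets,
        ephys_band_power=ephys_bp, ephys_times=ephys_times,
        ephys_wavelet=ephys_w if keep_wavelets else None,
    )
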