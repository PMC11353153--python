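"""Synthetic two-channel movies and coupled field-potential traces.

The generator emulates the measurement regimes the pipeline targets:
frame scans at 1 or 68 Hz and 60 s line scans at 125 Hz, with disk-shaped
somata on a noisy background. Calcium dynamics are modelled as sinusoidal
dF/F0 oscillations (the analysis surface is spectral, not event-based);
an optional exponential-transient mode supports event-flagging tests. A
"network source" — a slow-envelope sinusoid — can be shared between a
chosen subset of cells and the generated field potential, planting a known
imaging/ephys coupling. Astrocytes are marked by a bright static red
channel (emulating SR-101 uptake); neurons stay red-dim.

Everything is reproducible bit-exactly from the seed, and every quantity a
test might want back (centres, labels, frequencies, phases, couplings) is
returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .session import EphysRecording, ImagingSession

__all__ = ["GroundTruth", "make_movie", "make_ephys", "DEFAULT_FREQ_CHOICES"]

#: per-cell oscillation frequencies drawn when none are specified (Hz)
DEFAULT_FREQ_CHOICES = (1.0, 2.0, 3.0, 5.0)


@dataclass
class GroundTruth:
    """Everything that was planted in a synthetic session."""

    centres: np.ndarray  # (K, 2) float (row, col)
    radius: float
    labels: list  # 'astrocyte' | 'neuron' per cell
    freqs: np.ndarray  # Hz per cell
    amplitudes: np.ndarray  # dF/F0 units per cell
    phases: np.ndarray  # rad per cell
    baseline: float
    background: float
    rg_ratios: np.ndarray  # red/green intensity ratio per cell
    noise_sd: float
    coupled: tuple  # indices of cells sharing the network source
    network_freq: float
    network_phase: float
    envelope_freq: float
    envelope_depth: float
    fs: float
    duration_s: float
    seed: int
    transient_times: dict = field(default_factory=dict)  # cell -> event times (s)

    @property
    def n_cells(self) -> int:
        return len(self.labels)

    def cell_dff(self, t: np.ndarray) -> np.ndarray:
        """Noise-free dF/F0 of every cell at times ``t`` -> (len(t), K)."""
        out = np.zeros((len(t), self.n_cells))
        env = 1.0 + self.envelope_depth * np.sin(2 * np.pi * self.envelope_freq * t)
        for k in range(self.n_cells):
            if k in self.coupled:
                out[:, k] = self.amplitudes[k] * env * np.sin(
                    2 * np.pi * self.network_freq * t + self.network_phase)
            else:
                out[:, k] = self.amplitudes[k] * np.sin(
                    2 * np.pi * self.freqs[k] * t + self.phases[k])
            for t0 in self.transient_times.get(k, ()):  # optional calcium events
                rise = (t >= t0)
                out[rise, k] += self.amplitudes[k] * 10 * np.exp(-(t[rise] - t0) / 0.5)
        return out


def _place_cells(rng, n_cells, shape, radius, min_separation):
    h, w = shape
    margin = radius + 2
    if 2 * margin >= min(h, w):
        raise GenerationError(f"radius {radius} does not fit a {shape} frame")
    centres = []
    for _ in range(20000):
        if len(centres) == n_cells:
            break
        cand = rng.uniform([margin, margin], [h - margin, w - margin])
        if all(np.hypot(*(cand - c)) >= min_separation for c in centres):
            centres.append(cand)
    if len(centres) < n_cells:
        raise GenerationError(
            f"could not place {n_cells} non-overlapping cells of radius {radius} "
            f"in a {shape} frame")
    return np.asarray(centres)


def make_movie(n_cells: int = 20, shape=(128, 128), radius: float = 5.0,
               duration_s: float = 30.0, fs: float = 68.0, mode: str = "frame",
               amplitude: float = 0.2, cell_freqs=None, snr: float = 5.0,
               baseline: float = 100.0, background: float = 20.0,
               astro_fraction: float = 0.4, astro_rg_ratio: float = 3.0,
               neuron_rg_ratio: float = 0.25, n_channels: int = 2,
               coupled=(), network_freq: float = 3.0, envelope_freq: float = 0.1,
               envelope_depth: float = 0.8, transients=None,
               seed: int = 0):
    """Render a synthetic movie and its ground truth.

    Green channel: ``baseline * (1 + dff(t))`` on each disk, ``background``
    elsewhere, plus white Gaussian pixel noise with
    SD = (baseline - background) / snr (so ``snr`` is disk contrast over
    pixel noise). Red channel: static disks at each cell's planted
    red/green ratio. Cells in ``coupled`` share the slow-envelope network
    source at ``network_freq`` (see :func:`make_ephys`). Line mode renders
    two crossing chords per cell swept at ``fs`` lines/s.

    Returns ``(ImagingSession, GroundTruth)``.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * fs))
    if n_frames < 2:
        raise GenerationError("duration too short for the sampling rate")
    centres = _place_cells(rng, n_cells, shape, radius, min_separation=2 * radius + 4)
    labels = ["astrocyte" if rng.random() < astro_fraction else "neuron"
              for _ in range(n_cells)]
    if cell_freqs is None:
        choices = [f for f in DEFAULT_FREQ_CHOICES if f < 0.45 * fs]
        if not choices:
            choices = [0.2 * fs]
        freqs = rng.choice(choices, size=n_cells)
    else:
        freqs = np.broadcast_to(np.asarray(cell_freqs, dtype=np.float64), (n_cells,)).copy()
    if np.any(freqs >= fs / 2) or (coupled and network_freq >= fs / 2):
        raise GenerationError("planted frequencies must stay below Nyquist")
    amplitudes = np.full(n_cells, float(amplitude))
    phases = rng.uniform(0, 2 * np.pi, n_cells)
    rg = np.array([astro_rg_ratio if lab == "astrocyte" else neuron_rg_ratio
                   for lab in labels])
    noise_sd = (baseline - background) / snr
    truth = GroundTruth(
        centres=centres, radius=radius, labels=labels, freqs=freqs,
        amplitudes=amplitudes, phases=phases, baseline=baseline,
        background=background, rg_ratios=rg, noise_sd=noise_sd,
        coupled=tuple(coupled), network_freq=network_freq,
        network_phase=float(rng.uniform(0, 2 * np.pi)),
        envelope_freq=envelope_freq, envelope_depth=envelope_depth,
        fs=fs, duration_s=duration_s, seed=seed,
        transient_times=dict(transients or {}),
    )
    t = np.arange(n_frames) / fs
    dff = truth.cell_dff(t)  # (T, K)

    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    disk_masks = []
    for c in centres:
        disk_masks.append((rows - c[0]) ** 2 + (cols - c[1]) ** 2 <= radius ** 2)

    if mode == "frame":
        green = np.full((n_frames, h, w), background, dtype=np.float32)
        for k, m in enumerate(disk_masks):
            green[:, m] = baseline * (1.0 + dff[:, k, None]).astype(np.float32)
        green += noise_sd * rng.standard_normal(green.shape, dtype=np.float32)
        planes = [green]
        if n_channels == 2:
            red_base = np.full((h, w), background, dtype=np.float32)
            for k, m in enumerate(disk_masks):
                red_base[m] = baseline * rg[k]
            red = red_base[None] + noise_sd * rng.standard_normal(green.shape, dtype=np.float32)
            planes.append(red)
        stack = np.stack(planes, axis=-1)
        session = ImagingSession(stack=stack, sampling_interval=1.0 / fs,
                                 scan_mode="frame", source_path=f"synthetic_seed{seed}")
        return session, truth

    if mode != "line":
        raise GenerationError(f"unknown scan mode {mode!r}")

    # two crossing chords (horizontal + vertical diameter) per cell,
    # echoing the double-crossing scan paths used in vivo
    path = []
    path_cell = []
    r_int = int(round(radius))
    for k, c in enumerate(centres):
        cr, cc = int(round(c[0])), int(round(c[1]))
        for dc in range(-r_int, r_int + 1):
            path.append((cr, cc + dc))
            path_cell.append(k)
        for dr in range(-r_int, r_int + 1):
            path.append((cr + dr, cc))
            path_cell.append(k)
    path = np.asarray(path, dtype=np.int64)
    path_cell = np.asarray(path_cell)
    inside = np.array([disk_masks[path_cell[i]][tuple(path[i])] for i in range(len(path))])
    green = np.full((n_frames, 1, len(path)), background, dtype=np.float32)
    for k in range(n_cells):
        sel = (path_cell == k) & inside
        green[:, 0, sel] = baseline * (1.0 + dff[:, k, None]).astype(np.float32)
    green += noise_sd * rng.standard_normal(green.shape, dtype=np.float32)
    planes = [green]
    if n_channels == 2:
        red_line = np.full(len(path), background, dtype=np.float32)
        for k in range(n_cells):
            sel = (path_cell == k) & inside
            red_line[sel] = baseline * rg[k]
        red = red_line[None, None, :] + noise_sd * rng.standard_normal(green.shape, dtype=np.float32)
        planes.append(red)
    stack = np.stack(planes, axis=-1)
    session = ImagingSession(stack=stack, sampling_interval=1.0 / fs, scan_mode="line",
                             line_path=path, height=h, width=w,
                             source_path=f"synthetic_seed{seed}")
    return session, truth


def make_ephys(truth: GroundTruth, fs_native: float = 1250.0, pad_s: float = 5.0,
               tag: str = "imaging", gain: float = 1.0, noise_amp: float = 0.3,
               seed: int | None = None) -> EphysRecording:
    """Generate a raw LFP-like trace sharing the network source with the cells.

    The trace covers ``pad_s`` of padding on both sides of the imaging
    interval; a marker with ``tag`` sits at the imaging start. The signal
    is the amplitude-modulated network sinusoid (identical phase and
    envelope to the coupled cells, so imaging/ephys band powers correlate)
    plus 1/f noise. With no coupled cells the trace is pure 1/f noise.
    """
    if fs_native < 4 * truth.network_freq:
        raise GenerationError("fs_native too low for the network frequency")
    rng = np.random.default_rng(truth.seed + 7919 if seed is None else seed)
    total = truth.duration_s + 2 * pad_s
    n = int(round(total * fs_native))
    t = np.arange(n) / fs_native
    t_im = t - pad_s  # imaging time base: frame 0 at t = pad_s
    sig = np.zeros(n)
    if truth.coupled:
        env = 1.0 + truth.envelope_depth * np.sin(2 * np.pi * truth.envelope_freq * t_im)
        sig = gain * env * np.sin(2 * np.pi * truth.network_freq * t_im + truth.network_phase)
    # 1/f noise via spectral shaping of white noise
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs_native)
    f[0] = f[1]
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    pink *= noise_amp / pink.std()
    return EphysRecording(samples=sig + pink, sampling_rate=fs_native,
                          t0_offset=0.0, markers=[(pad_s, tag)],
                          native_rate=fs_native)
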