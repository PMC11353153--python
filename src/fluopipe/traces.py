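"""Per-cell fluorescence, dF/F0 and dG/R trace computation.

F is the mean intensity over each ROI's pixels per frame (or per scan line
for line-scan sessions). dF/F0 = (F - F0) / F0 on the background-corrected
green channel, with the baseline F0 averaged over a user-controllable
control range (default: the first 10% of frames). dG/R — the green-channel
change from the first frame divided by the red channel — is the
movement-robust alternative: a multiplicative artefact common to both
channels cancels in the ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .roi import ROISet

__all__ = ["TraceSet", "compute_F", "compute_dff", "compute_dgr", "smooth_traces",
           "default_control_range", "export_traces_csv"]


@dataclass
class TraceSet:
    """Per-cell time series: raw F plus derived dF/F0 and dG/R.

    ``F`` is ``[time, roi, channel]``; ``dff`` and ``dgr`` are
    ``[time, roi]``. ``roi_ids`` maps the roi axis back to ROI labels.
    """

    F: np.ndarray
    time_axis: np.ndarray
    roi_ids: list
    dff: np.ndarray | None = None
    dgr: np.ndarray | None = None
    F0: np.ndarray | None = None  # [roi] baseline of the corrected green trace
    control_range: tuple | None = None
    background_mode: str = "none"
    smoothing_window: int = 0

    @property
    def n_rois(self) -> int:
        return self.F.shape[1]

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.time_axis[1] - self.time_axis[0])

    def column(self, roi_id: int) -> int:
        return self.roi_ids.index(roi_id)

    def __eq__(self, other):
        if not isinstance(other, TraceSet):
            return NotImplemented
        def eq(a, b):
            if a is None or b is None:
                return (a is None) == (b is None)
            return np.array_equal(a, b, equal_nan=True)
        return (eq(self.F, other.F) and eq(self.dff, other.dff)
                and eq(self.dgr, other.dgr) and eq(self.F0, other.F0)
                and np.array_equal(self.time_axis, other.time_axis)
                and self.roi_ids == other.roi_ids
                and self.control_range == other.control_range
                and self.background_mode == other.background_mode
                and self.smoothing_window == other.smoothing_window)


def _included_rois(roiset: ROISet, include_all: bool):
    out = []
    for roi in roiset:
        lab = roiset.labels.get(roi.id)
        if not include_all and lab is not None and lab.value == "not_cell":
            continue
        out.append(roi)
    return out


def compute_F(session, roiset: ROISet, include_all: bool = False) -> TraceSet:
    """Mean fluorescence per ROI, frame and channel.

    ROIs labelled ``not_cell`` are excluded unless ``include_all`` is set;
    in line-scan mode an ROI with no mapped path pixels is dropped with a
    warning.
    """
    rois = _included_rois(roiset, include_all)
    T = session.n_frames
    C = session.n_channels
    used = []
    cols = []
    for roi in rois:
        if session.scan_mode == "line":
            idx = roi.line_pixel_indices
            if idx is None or len(idx) == 0:
                warnings.warn(f"ROI {roi.id} has no line-scan pixels; excluded from traces")
                continue
            cols.append(session.stack[:, 0, idx, :].mean(axis=1))
        else:
            cols.append(session.stack[:, roi.coords[:, 0], roi.coords[:, 1], :]
                        .astype(np.float64).mean(axis=1))
        used.append(roi.id)
    F = (np.stack(cols, axis=1) if cols else np.zeros((T, 0, C)))
    return TraceSet(F=F.astype(np.float64), time_axis=session.times, roi_ids=used)


def default_control_range(n_frames: int) -> tuple:
    """First 10% of frames, at least one frame."""
    return (0, max(1, n_frames // 10))


def compute_dff(traceset: TraceSet, session=None, roiset: ROISet | None = None,
                control_range: tuple | None = None, background="none",
                background_value=None, baseline_stat="mean") -> TraceSet:
    """Compute dF/F0 on the green channel with background correction.

    background modes: ``'auto'`` (per-frame mean of pixels outside every
    ROI; needs session+roiset), ``'manual_roi'`` (per-frame mean of a user
    mask passed as ``background_value``), ``'constant'`` (scalar
    ``background_value``), ``'none'``. An ROI whose corrected baseline F0
    is not positive gets NaN dF/F0 and a warning rather than an error.
    """
    T = traceset.F.shape[0]
    gi = session.channel_index("green") if session is not None else 0
    G = traceset.F[:, :, gi]
    if background == "none":
        B = np.zeros(T)
    elif background == "constant":
        if background_value is None:
            raise ValueError("constant background requires a value")
        B = np.full(T, float(background_value))
    elif background == "manual_roi":
        if background_value is None:
            raise ValueError("manual_roi background requires a mask")
        m = np.asarray(background_value, dtype=bool)
        if session is None:
            raise ValueError("manual_roi background requires the session")
        B = session.stack[:, :, :, gi][:, m].mean(axis=1)
    elif background == "auto":
        if session is None or roiset is None:
            raise ValueError("auto background requires the session and ROI set")
        outside = ~roiset.mask()
        if not outside.any():
            raise ValueError("no pixels outside ROIs for auto background")
        B = session.stack[:, :, :, gi][:, outside].mean(axis=1)
    else:
        raise ValueError(f"unknown background mode {background!r}")

    if control_range is None:
        control_range = default_control_range(T)
    c0, c1 = int(control_range[0]), int(control_range[1])
    if not (0 <= c0 < c1 <= T):
        raise ValueError(f"control range {control_range!r} outside [0, {T})")

    Fb = G - B[:, None]
    stat = np.mean if baseline_stat == "mean" else np.median
    F0 = stat(Fb[c0:c1], axis=0)
    dff = np.full_like(Fb, np.nan)
    ok = F0 > 0
    if not ok.all():
        bad = [traceset.roi_ids[k] for k in np.nonzero(~ok)[0]]
        warnings.warn(f"non-positive baseline F0 for ROIs {bad}; their dF/F0 is undefined")
    dff[:, ok] = (Fb[:, ok] - F0[ok]) / F0[ok]
    return replace(traceset, dff=dff, F0=F0, control_range=(c0, c1),
                   background_mode=background if isinstance(background, str) else "constant")


def compute_dgr(traceset: TraceSet, session=None) -> TraceSet:
    """Green-channel change from frame 0 divided by the red channel.

    dG/R[t,k] = (G[t,k] - G[0,k]) / R[t,k]; entries where the red channel
    is not positive are NaN with a warning.
    """
    gi = session.channel_index("green") if session is not None else 0
    ri = session.channel_index("red") if session is not None else 1
    if traceset.F.shape[2] < 2:
        raise ValueError("dG/R requires a two-channel session")
    G = traceset.F[:, :, gi]
    R = traceset.F[:, :, ri]
    dgr = np.full_like(G, np.nan)
    ok = R > 0
    if not ok.all():
        warnings.warn("red channel non-positive for some samples; dG/R undefined there")
    dgr[ok] = (G - G[0])[ok] / R[ok]
    return replace(traceset, dgr=dgr)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average along axis 0 with shrinking edge windows."""
    kernel = np.ones(window)
    counts = np.convolve(np.ones(x.shape[0]), kernel, mode="same")
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="same") / counts
    out = np.empty_like(x, dtype=np.float64)
    for k in range(x.shape[1]):
        out[:, k] = np.convolve(x[:, k], kernel, mode="same") / counts
    return out


def smooth_traces(traceset: TraceSet, window: int) -> TraceSet:
    """Smooth dF/F0 (and dG/R when present) with a centred moving average.

    ``window`` must be odd; edges use a shrinking window; window 1 is the
    identity.
    """
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window > traceset.F.shape[0]:
        raise ValueError("smoothing window longer than the trace")
    if window == 1:
        return replace(traceset, smoothing_window=1)
    out = replace(traceset, smoothing_window=window)
    if traceset.dff is not None:
        out.dff = _moving_average(traceset.dff, window)
    if traceset.dgr is not None:
        out.dgr = _moving_average(traceset.dgr, window)
    return out


def export_traces_csv(traceset: TraceSet, path):
    """Long-format CSV: time, roi_id, channel, F, dff, dgr."""
    import pandas as pd

    rows = []
    T, K, C = traceset.F.shape
    for k in range(K):
        for c in range(C):
            rows.append(pd.DataFrame({
                "time": traceset.time_axis,
                "roi_id": traceset.roi_ids[k],
                "channel": c,
                "F": traceset.F[:, k, c],
                "dff": traceset.dff[:, k] if (traceset.dff is not None and c == 0) else np.nan,
                "dgr": traceset.dgr[:, k] if (traceset.dgr is not None and c == 0) else np.nan,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path
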