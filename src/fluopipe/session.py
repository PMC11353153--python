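"""Session I/O: imaging movies, electrophysiology, and persistent analysis state.

An :class:`ImagingSession` wraps the raw movie (frame scan or line scan)
with its timing and channel metadata; an :class:`EphysRecording` holds the
aligned, 10x-decimated field-potential segment. A :class:`SessionState`
bundles the session with downstream products (ROIs, labels, traces) and
round-trips losslessly through a versioned HDF5 container.

Coordinates are 0-based (row, col) with the origin top-left; frame ``i``
is at ``t = i * sampling_interval`` seconds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import signal

from .errors import (
    AlignmentError,
    AmbiguousMarkerError,
    LoadError,
    MarkerNotFoundError,
    ROIImportError,
    SessionFormatError,
    UnsupportedFormatError,
)
from .roi import ROI, ROISet
from .classify import CellLabel

__all__ = [
    "ImagingSession",
    "EphysRecording",
    "SessionState",
    "load_image",
    "write_movie_tiff",
    "save_session",
    "load_session",
    "read_ephys_text",
    "write_ephys_text",
    "load_ephys",
    "find_segment_by_marker",
    "import_rois",
    "shift_rois",
    "DOWNSAMPLE_FACTOR",
]

SESSION_MAGIC = "fluopipe-session"
SESSION_VERSION = 1
#: ephys decimation factor applied on load
DOWNSAMPLE_FACTOR = 10


@dataclass
class ImagingSession:
    """One fluorescence movie with timing and channel metadata.

    ``stack`` is indexed ``(frame, row, col, channel)``. For line scans the
    "frames" are successive sweeps of the scan path: the stack has shape
    ``(n_lines, 1, n_path_pixels, n_channels)`` and ``line_path`` gives the
    (row, col) field-of-view coordinate of each path pixel; ``height`` and
    ``width`` then describe the field of view the path lives in.
    ``sampling_interval`` is seconds per frame (frame mode) or seconds per
    line (line mode).
    """

    stack: np.ndarray
    sampling_interval: float = 1.0
    scan_mode: str = "frame"
    channel_roles: dict = field(default_factory=dict)
    line_path: np.ndarray | None = None
    height: int | None = None
    width: int | None = None
    source_path: str = ""

    def __post_init__(self):
        self.stack = np.asarray(self.stack)
        if self.stack.ndim == 3:  # single channel without explicit axis
            self.stack = self.stack[..., np.newaxis]
        if self.stack.ndim != 4:
            raise ValueError("stack must be (frame, row, col, channel)")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.n_channels not in (1, 2):
            raise UnsupportedFormatError(f"{self.n_channels} channels unsupported (need 1 or 2)")
        if self.scan_mode not in ("frame", "line"):
            raise ValueError(f"unknown scan mode {self.scan_mode!r}")
        if not self.channel_roles:
            self.channel_roles = {"green": 0} if self.n_channels == 1 else {"green": 0, "red": 1}
        if self.scan_mode == "frame":
            if self.line_path is not None and len(self.line_path):
                raise ValueError("line_path only applies to line-scan sessions")
            self.line_path = None
            self.height = self.stack.shape[1]
            self.width = self.stack.shape[2]
        else:
            if self.line_path is None or len(self.line_path) == 0:
                raise ValueError("line-scan session requires a line_path")
            self.line_path = np.asarray(self.line_path, dtype=np.int64)
            if self.height is None or self.width is None:
                raise ValueError("line-scan session requires field-of-view height/width")
            if len(self.line_path) != self.stack.shape[2]:
                raise ValueError("line_path length must match stack width")
            r, c = self.line_path[:, 0], self.line_path[:, 1]
            if r.min() < 0 or c.min() < 0 or r.max() >= self.height or c.max() >= self.width:
                raise ValueError("line_path coordinates outside the field of view")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def n_channels(self) -> int:
        return self.stack.shape[3]

    @property
    def duration(self) -> float:
        return self.n_frames * self.sampling_interval

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.sampling_interval

    def channel_index(self, role: str) -> int:
        try:
            return self.channel_roles[role]
        except KeyError:
            raise KeyError(f"session has no {role!r} channel (roles: {self.channel_roles})")


@dataclass
class EphysRecording:
    """A voltage time series aligned to an imaging session.

    ``t0_offset`` is the time of sample 0 relative to imaging frame 0
    (0 after standard loading). ``markers`` are ``(time_s, tag)`` pairs on
    the recording's own time base.
    """

    samples: np.ndarray
    sampling_rate: float
    t0_offset: float = 0.0
    markers: list = field(default_factory=list)
    native_rate: float | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ephys samples must be finite")
        if self.native_rate is None:
            self.native_rate = self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0_offset + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class SessionState:
    """Everything the pipeline knows about one measurement."""

    session: ImagingSession
    rois: ROISet | None = None
    traces: "object | None" = None  # TraceSet; forward ref avoids cycle
    ephys: EphysRecording | None = None


# ---------------------------------------------------------------------------
# TIFF movies


def load_image(path, channel_roles=None, n_channels=None, interleave="alternate",
               sampling_interval=1.0, scan_mode="frame", line_path=None,
               height=None, width=None) -> ImagingSession:
    """Load a multipage TIFF movie into an :class:`ImagingSession`.

    Grayscale page stacks holding two channels may be interleaved page-wise
    (``'alternate'``: G,R,G,R,...) or stored as two half stacks
    (``'split'``). Pages with a trailing sample axis of 1 or 2 are used
    as-is. Missing timing metadata falls back to ``sampling_interval``
    (default 1.0 s).
    """
    import tifffile

    import logging

    path = Path(path)
    pages = []
    # tifffile reports corrupt/truncated structures through its logger and
    # silently drops the affected pages; promote those to hard load errors
    corruption: list[str] = []

    class _Trap(logging.Handler):
        def emit(self, record):
            msg = record.getMessage()
            if "invalid" in msg or "corrupt" in msg or "failed" in msg:
                corruption.append(msg)

    trap = _Trap()
    tlog = logging.getLogger("tifffile")
    tlog.addHandler(trap)
    try:
        with tifffile.TiffFile(path) as tf:
            n_pages = len(tf.pages)
            for i in range(n_pages):
                try:
                    pages.append(np.asarray(tf.pages[i].asarray()))
                except Exception as exc:
                    raise LoadError(f"cannot read page {i} of {path}: {exc}") from exc
    except LoadError:
        raise
    except Exception as exc:
        raise LoadError(f"cannot read TIFF {path}: {exc}") from exc
    finally:
        tlog.removeHandler(trap)
    if corruption:
        raise LoadError(
            f"corrupt TIFF {path} after page {len(pages)}: {corruption[0]}")
    if not pages:
        raise LoadError(f"{path} contains no pages")
    try:
        arr = np.stack(pages)
    except ValueError as exc:
        raise LoadError(f"pages of {path} have inconsistent shapes") from exc

    if arr.ndim == 4:  # pages already carry a sample/channel axis
        if arr.shape[-1] > 2:
            raise UnsupportedFormatError(f"{arr.shape[-1]} channels in {path}; at most 2 supported")
        stack = arr
    elif arr.ndim == 3:
        nc = n_channels or (len(channel_roles) if channel_roles else 1)
        if nc > 2:
            raise UnsupportedFormatError(f"{nc} channels requested; at most 2 supported")
        if nc == 2:
            if arr.shape[0] % 2:
                raise LoadError(f"{path}: odd page count {arr.shape[0]} for 2-channel movie")
            if interleave == "alternate":
                stack = np.stack([arr[0::2], arr[1::2]], axis=-1)
            elif interleave == "split":
                half = arr.shape[0] // 2
                stack = np.stack([arr[:half], arr[half:]], axis=-1)
            else:
                raise ValueError(f"unknown interleave dialect {interleave!r}")
        else:
            stack = arr[..., np.newaxis]
    else:
        raise UnsupportedFormatError(f"unexpected page dimensionality in {path}")

    return ImagingSession(
        stack=stack,
        sampling_interval=sampling_interval,
        scan_mode=scan_mode,
        channel_roles=dict(channel_roles) if channel_roles else {},
        line_path=line_path,
        height=height,
        width=width,
        source_path=str(path),
    )


def write_movie_tiff(session: ImagingSession, path, interleave="alternate"):
    """Write a session's stack as a multipage grayscale TIFF (inverse of load)."""
    import tifffile

    if session.n_channels == 2:
        g = session.stack[..., 0]
        r = session.stack[..., 1]
        if interleave == "alternate":
            pages = np.empty((2 * session.n_frames,) + g.shape[1:], dtype=session.stack.dtype)
            pages[0::2] = g
            pages[1::2] = r
        elif interleave == "split":
            pages = np.concatenate([g, r], axis=0)
        else:
            raise ValueError(f"unknown interleave dialect {interleave!r}")
    else:
        pages = session.stack[..., 0]
    tifffile.imwrite(path, pages, photometric="minisblack")


# ---------------------------------------------------------------------------
# Session container (HDF5)


def _write_str_attr(obj, key, value):
    obj.attrs[key] = np.bytes_(value.encode())


def save_session(state: SessionState, path):
    """Persist a :class:`SessionState` to a versioned HDF5 container."""
    from .traces import TraceSet  # local import; traces also imports session types

    path = Path(path)
    with h5py.File(path, "w") as f:
        _write_str_attr(f, "magic", SESSION_MAGIC)
        f.attrs["version"] = SESSION_VERSION
        s = state.session
        g = f.create_group("image")
        g.create_dataset("stack", data=s.stack)
        g.attrs["sampling_interval"] = s.sampling_interval
        _write_str_attr(g, "scan_mode", s.scan_mode)
        _write_str_attr(g, "source_path", s.source_path)
        g.attrs["height"] = s.height
        g.attrs["width"] = s.width
        _write_str_attr(g, "channel_roles", json.dumps(s.channel_roles))
        if s.line_path is not None:
            g.create_dataset("line_path", data=s.line_path)

        if state.rois is not None:
            rg = f.create_group("rois")
            rg.create_dataset("label_image", data=state.rois.label_image)
            for roi in state.rois:
                sub = rg.create_group(f"roi_{roi.id}")
                sub.attrs["id"] = roi.id
                sub.create_dataset("coords", data=roi.coords)
                _write_str_attr(sub, "flags", json.dumps(roi.flags))
                if roi.line_pixel_indices is not None:
                    sub.create_dataset("line_pixel_indices", data=roi.line_pixel_indices)
            if state.rois.labels:
                ids = sorted(state.rois.labels)
                lg = rg.create_group("labels")
                lg.create_dataset("roi_id", data=np.asarray(ids, dtype=np.int64))
                str_dt = h5py.string_dtype()
                lg.create_dataset("value", data=[state.rois.labels[i].value for i in ids], dtype=str_dt)
                lg.create_dataset("origin", data=[state.rois.labels[i].origin for i in ids], dtype=str_dt)

        if state.traces is not None:
            t = state.traces
            tg = f.create_group("traces")
            tg.create_dataset("F", data=t.F)
            tg.create_dataset("time_axis", data=t.time_axis)
            tg.create_dataset("roi_ids", data=np.asarray(t.roi_ids, dtype=np.int64))
            if t.dff is not None:
                tg.create_dataset("dff", data=t.dff)
            if t.dgr is not None:
                tg.create_dataset("dgr", data=t.dgr)
            if t.F0 is not None:
                tg.create_dataset("F0", data=t.F0)
            if t.control_range is not None:
                tg.attrs["control_range"] = np.asarray(t.control_range, dtype=np.int64)
            _write_str_attr(tg, "background_mode", t.background_mode or "none")
            tg.attrs["smoothing_window"] = t.smoothing_window

        if state.ephys is not None:
            e = state.ephys
            eg = f.create_group("ephys")
            eg.create_dataset("samples", data=e.samples)
            eg.attrs["sampling_rate"] = e.sampling_rate
            eg.attrs["t0_offset"] = e.t0_offset
            eg.attrs["native_rate"] = e.native_rate
            _write_str_attr(eg, "markers", json.dumps([[float(t_), tag] for t_, tag in e.markers]))
    return path


def _read_str_attr(obj, key):
    v = obj.attrs[key]
    return v.decode() if isinstance(v, bytes) else str(v)


def load_session(path) -> SessionState:
    """Load a container written by :func:`save_session` (version checked)."""
    from .traces import TraceSet

    path = Path(path)
    try:
        f = h5py.File(path, "r")
    except Exception as exc:
        raise SessionFormatError(f"cannot open {path} as a session container: {exc}") from exc
    with f:
        magic = _read_str_attr(f, "magic") if "magic" in f.attrs else None
        if magic != SESSION_MAGIC:
            raise SessionFormatError(
                f"{path} is not a fluopipe session (magic={magic!r})",
                found=magic, expected=SESSION_MAGIC)
        version = int(f.attrs.get("version", -1))
        if version != SESSION_VERSION:
            raise SessionFormatError(
                f"{path}: unsupported session schema version {version} "
                f"(this build reads version {SESSION_VERSION})",
                found=version, expected=SESSION_VERSION)

        g = f["image"]
        line_path = g["line_path"][()] if "line_path" in g else None
        session = ImagingSession(
            stack=g["stack"][()],
            sampling_interval=float(g.attrs["sampling_interval"]),
            scan_mode=_read_str_attr(g, "scan_mode"),
            channel_roles=json.loads(_read_str_attr(g, "channel_roles")),
            line_path=line_path,
            height=int(g.attrs["height"]),
            width=int(g.attrs["width"]),
            source_path=_read_str_attr(g, "source_path"),
        )

        rois = None
        if "rois" in f:
            rg = f["rois"]
            label_image = rg["label_image"][()]
            base = ROISet.from_label_image(label_image)
            for roi in base:
                sub = rg[f"roi_{roi.id}"]
                roi.flags = json.loads(_read_str_attr(sub, "flags"))
                if "line_pixel_indices" in sub:
                    roi.line_pixel_indices = sub["line_pixel_indices"][()]
            labels = {}
            if "labels" in rg:
                lg = rg["labels"]
                for rid, val, orig in zip(lg["roi_id"][()], lg["value"][()], lg["origin"][()]):
                    val = val.decode() if isinstance(val, bytes) else val
                    orig = orig.decode() if isinstance(orig, bytes) else orig
                    labels[int(rid)] = CellLabel(val, orig)
            base.labels = labels
            rois = base

        traces = None
        if "traces" in f:
            tg = f["traces"]
            traces = TraceSet(
                F=tg["F"][()],
                time_axis=tg["time_axis"][()],
                roi_ids=[int(i) for i in tg["roi_ids"][()]],
                dff=tg["dff"][()] if "dff" in tg else None,
                dgr=tg["dgr"][()] if "dgr" in tg else None,
                F0=tg["F0"][()] if "F0" in tg else None,
                control_range=tuple(int(v) for v in tg.attrs["control_range"])
                if "control_range" in tg.attrs else None,
                background_mode=_read_str_attr(tg, "background_mode"),
                smoothing_window=int(tg.attrs["smoothing_window"]),
            )

        ephys = None
        if "ephys" in f:
            eg = f["ephys"]
            ephys = EphysRecording(
                samples=eg["samples"][()],
                sampling_rate=float(eg.attrs["sampling_rate"]),
                t0_offset=float(eg.attrs["t0_offset"]),
                native_rate=float(eg.attrs["native_rate"]),
                markers=[(float(t_), str(tag)) for t_, tag in json.loads(_read_str_attr(eg, "markers"))],
            )

    return SessionState(session=session, rois=rois, traces=traces, ephys=ephys)


# ---------------------------------------------------------------------------
# Electrophysiology


def read_ephys_text(path) -> EphysRecording:
    """Read the plain-text ephys interchange format.

    Two whitespace- or comma-separated columns (time s, value); header
    comment lines of the form ``# marker: <time_s> <tag>`` declare tagged
    markers. The sampling rate is inferred from the time column.
    """
    path = Path(path)
    markers = []
    times = []
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("marker:"):
                    parts = body[len("marker:"):].split()
                    if len(parts) >= 2:
                        markers.append((float(parts[0]), " ".join(parts[1:])))
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise LoadError(f"{path}:{lineno}: expected two columns, got {line!r}")
            times.append(float(parts[0]))
            values.append(float(parts[1]))
    if len(times) < 2:
        raise LoadError(f"{path}: need at least two samples")
    times = np.asarray(times)
    dt = np.median(np.diff(times))
    if dt <= 0:
        raise LoadError(f"{path}: time column is not increasing")
    rate = 1.0 / dt
    return EphysRecording(samples=np.asarray(values), sampling_rate=rate,
                          t0_offset=float(times[0]), markers=markers, native_rate=rate)


def write_ephys_text(rec: EphysRecording, path):
    """Write a recording in the plain-text interchange format."""
    path = Path(path)
    t = rec.times
    with open(path, "w") as fh:
        fh.write("# fluopipe ephys v1\n")
        for mt, tag in rec.markers:
            fh.write(f"# marker: {mt} {tag}\n")
        np.savetxt(fh, np.column_stack([t, rec.samples]), fmt="%.9g")
    return path


def find_segment_by_marker(ephys: EphysRecording, tag: str, duration: float):
    """Return the (start, end) seconds delimited by a tagged marker.

    The marker time is the segment start; the segment length is the imaging
    duration. A missing tag raises :class:`MarkerNotFoundError`; a tag that
    occurs more than once raises :class:`AmbiguousMarkerError` listing every
    occurrence.
    """
    if not ephys.markers:
        raise MarkerNotFoundError("recording has no markers")
    hits = [t for t, m in ephys.markers if m == tag]
    if not hits:
        available = sorted({m for _, m in ephys.markers})
        raise MarkerNotFoundError(f"marker {tag!r} not found (available: {available})")
    if len(hits) > 1:
        raise AmbiguousMarkerError(f"marker {tag!r} occurs {len(hits)} times, at t = {hits}")
    return (hits[0], hits[0] + duration)


def load_ephys(path_or_rec, session: ImagingSession, marker: str | None = None,
               factor: int = DOWNSAMPLE_FACTOR) -> EphysRecording:
    """Extract, align and decimate the ephys segment matching a session.

    The segment starts at the tagged marker when ``marker`` is given,
    otherwise at the start of the recording, and spans the imaging
    duration. It is low-pass filtered (order-8 Chebyshev-I at 0.8x the
    target Nyquist, zero phase) and decimated by ``factor`` (10 by
    default), and returned with sample 0 aligned to imaging frame 0.
    """
    raw = path_or_rec if isinstance(path_or_rec, EphysRecording) else read_ephys_text(path_or_rec)
    if marker is not None:
        start, end = find_segment_by_marker(raw, marker, session.duration)
    else:
        # no marker: imaging frame 0 sits at t = 0 on the shared clock
        start, end = 0.0, session.duration
    rec_start, rec_end = raw.t0_offset, raw.t0_offset + raw.duration
    if end <= rec_start or start >= rec_end:
        raise AlignmentError(
            f"imaging interval [{start:.3f}, {end:.3f}] s does not overlap "
            f"recording [{rec_start:.3f}, {rec_end:.3f}] s")
    i0 = max(0, int(round((start - raw.t0_offset) * raw.sampling_rate)))
    n = int(round(session.duration * raw.sampling_rate))
    seg = raw.samples[i0:i0 + n]
    if len(seg) < n:
        warnings.warn(f"ephys covers only {len(seg)/raw.sampling_rate:.2f} s of the "
                      f"{session.duration:.2f} s imaging interval")
    if len(seg) < 3 * factor:
        raise AlignmentError("aligned ephys segment too short to decimate")
    out = signal.decimate(seg, factor, zero_phase=True)
    return EphysRecording(samples=out, sampling_rate=raw.sampling_rate / factor,
                          t0_offset=0.0, markers=list(raw.markers),
                          native_rate=raw.sampling_rate)


# ---------------------------------------------------------------------------
# ROI re-use across sessions


def import_rois(session: ImagingSession, other_session_path) -> ROISet:
    """Bring the ROI set of a previously analysed session onto this one."""
    other = load_session(other_session_path)
    if other.rois is None:
        raise ROIImportError(f"{other_session_path} contains no ROIs")
    shape = other.rois.label_image.shape
    if shape != (session.height, session.width):
        raise ROIImportError(
            f"ROI image shape {shape} does not match target "
            f"({session.height}, {session.width})")
    return other.rois


def shift_rois(roiset: ROISet, dy: int, dx: int, min_area: int = 100) -> ROISet:
    """Rigidly translate every ROI by integer pixels (dy rows, dx cols).

    Pixels shifted off-image are dropped; an ROI whose remaining area falls
    below ``min_area`` (the validation minimum) is flagged ``clipped``.
    Label identities are preserved.
    """
    dy, dx = int(dy), int(dx)
    h, w = roiset.label_image.shape
    label_image = np.zeros_like(roiset.label_image)
    new_rois = []
    for roi in roiset:
        coords = roi.coords + np.array([dy, dx], dtype=np.int64)
        inside = ((coords[:, 0] >= 0) & (coords[:, 0] < h)
                  & (coords[:, 1] >= 0) & (coords[:, 1] < w))
        coords = coords[inside]
        flags = [fl for fl in roi.flags if fl != "clipped"]
        if len(coords) < min_area:
            flags = flags + ["clipped"]
        if len(coords):
            label_image[coords[:, 0], coords[:, 1]] = roi.id
            sub = np.zeros((h, w), dtype=np.int32)
            sub[coords[:, 0], coords[:, 1]] = 1
            p = measure_region(sub)
            new_rois.append(ROI(id=roi.id, coords=coords,
                                centroid=p["centroid"], eccentricity=p["eccentricity"],
                                bbox=p["bbox"], line_pixel_indices=roi.line_pixel_indices,
                                flags=flags))
        else:
            new_rois.append(ROI(id=roi.id, coords=coords.reshape(0, 2),
                                centroid=(float("nan"), float("nan")), eccentricity=float("nan"),
                                bbox=(0, 0, 0, 0), line_pixel_indices=roi.line_pixel_indices,
                                flags=flags))
    out = ROISet.__new__(ROISet)
    out.label_image = label_image
    out.rois = new_rois
    out.labels = dict(roiset.labels)
    return out


def measure_region(mask01: np.ndarray) -> dict:
    """Geometry of a single binary region (centroid, eccentricity, bbox)."""
    from skimage import measure as skmeasure

    props = skmeasure.regionprops(mask01)
    p = props[0]
    return {
        "centroid": tuple(float(c) for c in p.centroid),
        "eccentricity": float(p.eccentricity),
        "bbox": tuple(int(b) for b in p.bbox),
    }
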