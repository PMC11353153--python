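"""HTML report generation and folder-level batch processing.

Reports are deliberately plain: one self-contained HTML file per session
plus PNG panels in a sibling directory, so they diff cleanly and carry no
timestamps. The per-cell report mirrors the classic layout — field-of-view
location, channel crops, the dF/F0 trace and one wavelet panel per band —
and flags candidate calcium events where dF/F0 exceeds the trace median by
k median absolute deviations (k = 5 by default). The network report stacks
every cell's band power, colour-coded by type (astrocytes red, neurons
green, other regions blue), over the ephys band power on a shared time
axis, and tabulates each cell's correlation with the ephys.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import CatalogueError, StageNotRunError
from .session import SessionState, load_session
from .spectral import DEFAULT_BANDS, analyze_session
from .sync import plv_matrix, xcorr_matrices

__all__ = [
    "report_cells",
    "report_network",
    "SessionCollection",
    "load_data_from_folder",
    "apply",
    "flag_events",
    "OPERATIONS",
]

LABEL_COLOURS = {"astrocyte": "tab:red", "neuron": "tab:green"}
FALLBACK_COLOUR = "tab:blue"


def flag_events(dff: np.ndarray, k: float = 5.0) -> np.ndarray:
    """Boolean event mask: dF/F0 more than k MADs above the trace median."""
    x = np.asarray(dff, dtype=np.float64)
    med = np.nanmedian(x)
    mad = np.nanmedian(np.abs(x - med))
    return x > med + k * mad


def _require(state: SessionState, stage: str):
    if stage == "rois" and state.rois is None:
        raise StageNotRunError("rois")
    if stage == "traces" and (state.traces is None or state.traces.dff is None):
        raise StageNotRunError("traces")


def _save_panel(fig, path: Path):
    fig.savefig(path, dpi=90, metadata={"Software": None})
    plt.close(fig)


def _event_count(dff_col, k):
    mask = flag_events(dff_col, k)
    # count rising edges so a multi-sample transient is one event
    return int(np.sum(mask[1:] & ~mask[:-1]) + (1 if mask[0] else 0))


def report_cells(state: SessionState, out_path, bands=DEFAULT_BANDS,
                 mad_k: float = 5.0, make_figures: bool = True) -> Path:
    """Write the per-cell HTML report; returns the HTML path.

    Requires ROIs and dF/F0 traces (a missing stage raises
    :class:`StageNotRunError` naming it); wavelet panels are computed here
    from the stored traces. Ephys information is included when present and
    silently omitted otherwise.
    """
    _require(state, "rois")
    _require(state, "traces")
    out_path = Path(out_path)
    fig_dir = out_path.with_suffix("")
    if make_figures:
        fig_dir.mkdir(parents=True, exist_ok=True)
    ts = state.traces
    spectra = analyze_session(ts, state.ephys, bands=bands, keep_wavelets=False)

    s = state.session
    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>"
             "<title>fluopipe cell report</title></head><body>"]
    parts.append("<h1>Cell report</h1>")
    parts.append("<h2>Imaging settings</h2><ul>")
    parts.append(f"<li>source: {html.escape(s.source_path)}</li>")
    parts.append(f"<li>scan mode: {s.scan_mode}; frames: {s.n_frames}; "
                 f"sampling interval: {s.sampling_interval:.6g} s "
                 f"({1.0 / s.sampling_interval:.4g} Hz)</li>")
    parts.append(f"<li>channels: {s.n_channels} ({', '.join(s.channel_roles)})</li>")
    if ts.control_range is not None:
        parts.append(f"<li>F0 control range: frames {ts.control_range[0]}-{ts.control_range[1]}; "
                     f"background: {ts.background_mode}</li>")
    if state.ephys is not None:
        e = state.ephys
        parts.append(f"<li>ephys: {len(e.samples)} samples at {e.sampling_rate:.4g} Hz "
                     f"(native {e.native_rate:.4g} Hz)</li>")
    parts.append("</ul>")

    # summary table with the MAD event flags as the spike-detection column
    parts.append("<h2>Summary</h2><table border='1'><tr><th>ROI</th><th>label</th>"
                 "<th>origin</th><th>area (px)</th><th>eccentricity</th>"
                 "<th>events (&gt;%.3g MAD)</th></tr>" % mad_k)
    roi_by_id = {r.id: r for r in state.rois}
    for j, rid in enumerate(ts.roi_ids):
        roi = roi_by_id[rid]
        lab = state.rois.labels.get(rid)
        n_ev = _event_count(ts.dff[:, j], mad_k)
        parts.append(f"<tr><td>{rid}</td><td>{lab.value if lab else 'unlabelled'}</td>"
                     f"<td>{lab.origin if lab else '-'}</td><td>{roi.area}</td>"
                     f"<td>{roi.eccentricity:.3f}</td><td>{n_ev}</td></tr>")
    parts.append("</table>")

    for j, rid in enumerate(ts.roi_ids):
        roi = roi_by_id[rid]
        lab = state.rois.labels.get(rid)
        parts.append(f"<h2>Cell {rid}</h2>")
        parts.append(f"<p>label: {lab.value if lab else 'unlabelled'} "
                     f"({lab.origin if lab else '-'}); area {roi.area} px; "
                     f"centroid ({roi.centroid[0]:.1f}, {roi.centroid[1]:.1f}); "
                     f"eccentricity {roi.eccentricity:.3f}</p>")
        if make_figures and state.session.scan_mode == "frame":
            fig, axes = plt.subplots(1, 3, figsize=(9, 3))
            ref = state.session.stack[..., 0].mean(axis=0)
            axes[0].imshow(ref, cmap="gray")
            r0, c0, r1, c1 = roi.bbox
            axes[0].add_patch(plt.Rectangle((c0, r0), c1 - c0, r1 - r0,
                                            fill=False, edgecolor="w"))
            axes[0].set_title("field of view")
            axes[1].imshow(state.session.stack[:, r0:r1, c0:c1, 0].mean(axis=0), cmap="Greens_r")
            axes[1].set_title("green")
            if state.session.n_channels == 2:
                axes[2].imshow(state.session.stack[:, r0:r1, c0:c1, 1].mean(axis=0), cmap="Reds_r")
            axes[2].set_title("red")
            for ax in axes:
                ax.set_xticks([]), ax.set_yticks([])
            loc_png = fig_dir / f"cell_{rid}_location.png"
            _save_panel(fig, loc_png)
            parts.append(f"<img src='{fig_dir.name}/{loc_png.name}' alt='cell {rid} location'>")
        if make_figures:
            fig, axes = plt.subplots(len(bands) + 1, 1, figsize=(7, 1.6 * (len(bands) + 1)),
                                     sharex=True)
            axes[0].plot(ts.time_axis, ts.dff[:, j], lw=0.7, color="k")
            ev = flag_events(ts.dff[:, j], mad_k)
            if ev.any():
                axes[0].plot(ts.time_axis[ev], ts.dff[ev, j], "r.", ms=3)
            axes[0].set_ylabel("dF/F0")
            for bi, band in enumerate(bands):
                axes[bi + 1].plot(spectra.cell_times, spectra.cell_band_power[j, bi],
                                  lw=0.7)
                axes[bi + 1].set_ylabel(band.name)
            axes[-1].set_xlabel("time (s)")
            panel_png = fig_dir / f"cell_{rid}_bands.png"
            _save_panel(fig, panel_png)
            parts.append(f"<img src='{fig_dir.name}/{panel_png.name}' alt='cell {rid} bands'>")
        else:
            for band in bands:
                parts.append(f"<div class='band-panel' data-cell='{rid}' "
                             f"data-band='{band.name}'></div>")
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts))
    return out_path


def _ephys_correlations(spectra):
    """Pearson r of each cell's band power with the ephys band power."""
    if spectra.ephys_band_power is None:
        return None
    K, B, _ = spectra.cell_band_power.shape
    out = np.full((K, B), np.nan)
    for bi in range(B):
        e = np.interp(spectra.cell_times, spectra.ephys_times,
                      spectra.ephys_band_power[bi])
        for k in range(K):
            c = spectra.cell_band_power[k, bi]
            if c.std() > 0 and e.std() > 0:
                out[k, bi] = float(np.corrcoef(c, e)[0, 1])
    return out


def report_network(state: SessionState, out_path, bands=DEFAULT_BANDS,
                   make_figures: bool = True) -> Path:
    """Write the network HTML report (stacked band powers, ephys beneath)."""
    _require(state, "rois")
    _require(state, "traces")
    out_path = Path(out_path)
    fig_dir = out_path.with_suffix("")
    if make_figures:
        fig_dir.mkdir(parents=True, exist_ok=True)
    ts = state.traces
    spectra = analyze_session(ts, state.ephys, bands=bands)
    corr = _ephys_correlations(spectra)

    parts = ["<!DOCTYPE html><html><head><meta charset='utf-8'>"
             "<title>fluopipe network report</title></head><body>"]
    parts.append("<h1>Network report</h1>")
    for bi, band in enumerate(bands):
        parts.append(f"<h2>{band.name} band ({band.f_low}-{band.f_high} Hz)</h2>")
        if make_figures:
            n_rows = len(ts.roi_ids) + (1 if spectra.ephys_band_power is not None else 0)
            fig, ax = plt.subplots(figsize=(8, max(2, 0.45 * n_rows)))
            offset = 0.0
            yticks, ylabels = [], []
            for k, rid in enumerate(ts.roi_ids):
                lab = state.rois.labels.get(rid)
                colour = LABEL_COLOURS.get(lab.value if lab else "", FALLBACK_COLOUR)
                p = spectra.cell_band_power[k, bi]
                scale = p.max() if p.max() > 0 else 1.0
                ax.plot(spectra.cell_times, offset + p / scale, color=colour, lw=0.7)
                yticks.append(offset)
                ylabels.append(f"cell {rid}")
                offset += 1.2
            if spectra.ephys_band_power is not None:
                e = spectra.ephys_band_power[bi]
                ax.plot(spectra.ephys_times, offset + e / (e.max() or 1.0),
                        color="k", lw=0.7)
                yticks.append(offset)
                ylabels.append("ephys")
            ax.set_yticks(yticks, ylabels)
            ax.set_xlabel("time (s)")
            png = fig_dir / f"network_{band.name}.png"
            _save_panel(fig, png)
            parts.append(f"<img src='{fig_dir.name}/{png.name}' alt='{band.name} band'>")
    parts.append("<h2>Cell/ephys band-power correlation</h2>")
    if corr is None:
        parts.append("<p>no ephys recording loaded</p>")
    else:
        parts.append("<table border='1'><tr><th>ROI</th><th>label</th>"
                     + "".join(f"<th>r ({b.name})</th>" for b in bands) + "</tr>")
        for k, rid in enumerate(ts.roi_ids):
            lab = state.rois.labels.get(rid)
            if lab is None:
                import warnings
                warnings.warn(f"ROI {rid} has no label; rendered as non-cell")
            cells = "".join(f"<td>{corr[k, bi]:.3f}</td>" for bi in range(len(bands)))
            parts.append(f"<tr><td>{rid}</td>"
                         f"<td>{lab.value if lab else 'unlabelled'}</td>{cells}</tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts))
    return out_path


# ---------------------------------------------------------------------------
# batch processing


@dataclass
class SessionCollection:
    """Sessions loaded from one folder, in lexicographic filename order."""

    sessions: list  # (id, SessionState)
    folder: str = ""
    failures: dict = field(default_factory=dict)  # id -> error string

    @property
    def ids(self):
        return [sid for sid, _ in self.sessions]

    def __len__(self):
        return len(self.sessions)


def load_data_from_folder(folder, pattern: str = "*.h5") -> SessionCollection:
    """Load every session container in a folder (errors recorded, not fatal)."""
    folder = Path(folder)
    paths = sorted(folder.glob(pattern))
    if not paths:
        raise CatalogueError(f"no session containers matching {pattern!r} in {folder}")
    sessions, failures = [], {}
    for p in paths:
        try:
            sessions.append((p.stem, load_session(p)))
        except Exception as exc:  # fault isolation: one bad file must not abort
            failures[p.stem] = f"{type(exc).__name__}: {exc}"
    return SessionCollection(sessions=sessions, folder=str(folder), failures=failures)


def _op_band_summary(state: SessionState, bands=DEFAULT_BANDS, **kw):
    _require(state, "traces")
    spectra = analyze_session(state.traces, state.ephys, bands=bands)
    row = {"n_cells": len(spectra.cell_ids)}
    for bi, b in enumerate(bands):
        row[f"{b.name}_power_mean"] = float(spectra.cell_band_power[:, bi, :].mean()) \
            if len(spectra.cell_ids) else float("nan")
    return row


def _op_event_counts(state: SessionState, mad_k: float = 5.0, **kw):
    _require(state, "traces")
    ts = state.traces
    counts = [_event_count(ts.dff[:, j], mad_k) for j in range(ts.dff.shape[1])]
    return {"n_cells": len(counts), "total_events": int(sum(counts))}


def _op_plv_summary(state: SessionState, band=DEFAULT_BANDS[0], **kw):
    _require(state, "traces")
    m = plv_matrix(state.traces, band)
    K = m.values.shape[0]
    off = m.values[np.triu_indices(K, 1)] if K > 1 else np.array([np.nan])
    return {"n_cells": K, "plv_mean": float(np.nanmean(off))}


def _op_label_counts(state: SessionState, **kw):
    _require(state, "rois")
    row = {"n_rois": len(state.rois)}
    for v in ("astrocyte", "neuron", "not_cell", "unclassified"):
        row[v] = sum(1 for lab in state.rois.labels.values() if lab.value == v)
    return row


OPERATIONS = {
    "band_summary": _op_band_summary,
    "event_counts": _op_event_counts,
    "plv_summary": _op_plv_summary,
    "label_counts": _op_label_counts,
}


def apply(collection: SessionCollection, operation: str, **params) -> pd.DataFrame:
    """Run one catalogue operation on every session of a collection.

    Results come back as a DataFrame indexed by session id; a failure on
    one session is recorded in ``collection.failures`` and does not abort
    the rest. Unknown operation names raise :class:`CatalogueError` listing
    the catalogue.
    """
    if operation not in OPERATIONS:
        raise CatalogueError(
            f"unknown operation {operation!r}; valid: {sorted(OPERATIONS)}")
    fn = OPERATIONS[operation]
    rows = {}
    for sid, state in collection.sessions:
        try:
            rows[sid] = fn(state, **params)
        except Exception as exc:
            collection.failures[sid] = f"{type(exc).__name__}: {exc}"
    return pd.DataFrame.from_dict(rows, orient="index")
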