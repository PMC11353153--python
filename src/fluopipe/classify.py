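"""Cell validation and astrocyte/neuron classification.

An ROI is accepted as a cell when its area exceeds 100 px, its
eccentricity is below 0.85 (somata are roughly circular) and its mean
fluorescence is at least twice that of its immediate vicinity. Valid cells
are then split by the red/green intensity ratio: the red channel carries an
astrocyte-specific marker (e.g. SR-101) while the green channel carries the
calcium indicator (OGB-1, GCaMP), so a high red/green ratio indicates an
astrocyte and a low one a neuron. Ratios between the two decision
boundaries are left ``unclassified`` for manual review; manual and imported
labels always take precedence over automatic ones.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import AnnotationImportError
from .roi import ROI, ROISet, ReferenceImage

__all__ = [
    "ClassificationParams",
    "CellLabel",
    "LABEL_VALUES",
    "validate_roi",
    "classify_cells",
    "override_label",
    "export_cell_images",
    "import_annotations",
]

LABEL_VALUES = ("astrocyte", "neuron", "not_cell", "unclassified")


@dataclass
class ClassificationParams:
    """Validation and classification thresholds.

    Validation follows the published rules verbatim: area strictly greater
    than ``min_area``, eccentricity strictly lower than ``max_eccentricity``,
    in-ROI mean at least ``min_contrast_ratio`` times the vicinity mean.
    The red/green ratio boundaries are deliberately separated so that
    ambiguous cells land in ``unclassified`` rather than being forced into a
    class.
    """

    min_area: int = 100
    max_eccentricity: float = 0.85
    min_contrast_ratio: float = 2.0
    vicinity_width: int = 5
    astro_red_green_ratio_min: float = 1.5
    neuron_red_green_ratio_max: float = 0.75

    def __post_init__(self):
        if min(self.min_area, self.max_eccentricity, self.min_contrast_ratio,
               self.vicinity_width, self.astro_red_green_ratio_min,
               self.neuron_red_green_ratio_max) <= 0:
            raise ValueError("all classification parameters must be positive")
        if self.max_eccentricity >= 1:
            raise ValueError("max_eccentricity must be < 1")
        if self.astro_red_green_ratio_min <= self.neuron_red_green_ratio_max:
            raise ValueError("astro ratio boundary must exceed neuron boundary")


@dataclass(frozen=True)
class CellLabel:
    value: str  # astrocyte | neuron | not_cell | unclassified
    origin: str = "auto"  # auto | manual | imported

    def __post_init__(self):
        if self.value not in LABEL_VALUES:
            raise ValueError(f"unknown label value {self.value!r}")
        if self.origin not in ("auto", "manual", "imported"):
            raise ValueError(f"unknown label origin {self.origin!r}")


def _vicinity_mask(roi: ROI, shape, width: int, exclude=None) -> np.ndarray:
    """Ring of ``width`` px around the ROI, minus the ROI and any ``exclude`` mask."""
    m = roi.mask(shape)
    dilated = ndimage.binary_dilation(m, iterations=width)
    ring = dilated & ~m
    if exclude is not None:
        ring &= ~exclude
    return ring


def validate_roi(roi: ROI, ref_green: ReferenceImage, params: ClassificationParams | None = None,
                 roiset: ROISet | None = None):
    """Decide whether an ROI is a cell; return ``(is_cell, failed_criteria)``.

    The vicinity used for the contrast test is a ring ``vicinity_width`` px
    wide around the ROI with all other ROIs excluded, so neighbouring cells
    do not inflate the background estimate.
    """
    params = params or ClassificationParams()
    img = np.asarray(ref_green.pixels, dtype=np.float64)
    reasons = []
    if not roi.area > params.min_area:
        reasons.append("area")
    if not roi.eccentricity < params.max_eccentricity:
        reasons.append("eccentricity")
    exclude = roiset.mask() if roiset is not None else None
    ring = _vicinity_mask(roi, img.shape, params.vicinity_width, exclude=exclude)
    if not ring.any():
        raise ValueError(f"ROI {roi.id} has an empty vicinity (fills the image)")
    inside = img[roi.coords[:, 0], roi.coords[:, 1]].mean()
    vicinity = img[ring].mean()
    if not inside >= params.min_contrast_ratio * vicinity:
        reasons.append("contrast")
    return (len(reasons) == 0), reasons


def _roi_channel_mean(roi: ROI, ref: ReferenceImage) -> float:
    return float(np.asarray(ref.pixels, dtype=np.float64)[roi.coords[:, 0], roi.coords[:, 1]].mean())


def classify_cells(session, roiset: ROISet, ref_green: ReferenceImage,
                   ref_red: ReferenceImage | None = None,
                   params: ClassificationParams | None = None) -> dict:
    """Label every ROI as astrocyte / neuron / not_cell / unclassified.

    Invalid ROIs become ``not_cell`` regardless of channel ratios. Valid
    cells in a two-channel session are split on mean(red)/mean(green) over
    the ROI pixels of the reference images; single-channel sessions leave
    valid cells ``unclassified``. Existing manual or imported labels are
    never overwritten. Updates ``roiset.labels`` in place and returns it.
    """
    params = params or ClassificationParams()
    if session.n_channels == 2 and ref_red is None:
        raise ValueError("two-channel session requires a red reference image")
    for roi in roiset:
        prior = roiset.labels.get(roi.id)
        if prior is not None and prior.origin in ("manual", "imported"):
            continue
        ok, _ = validate_roi(roi, ref_green, params, roiset=roiset)
        if not ok:
            roiset.labels[roi.id] = CellLabel("not_cell", "auto")
            continue
        if session.n_channels < 2 or ref_red is None:
            roiset.labels[roi.id] = CellLabel("unclassified", "auto")
            continue
        g = _roi_channel_mean(roi, ref_green)
        r = _roi_channel_mean(roi, ref_red)
        if g <= 0:
            value = "astrocyte" if r > 0 else "unclassified"
        else:
            ratio = r / g
            if ratio >= params.astro_red_green_ratio_min:
                value = "astrocyte"
            elif ratio <= params.neuron_red_green_ratio_max:
                value = "neuron"
            else:
                value = "unclassified"
        roiset.labels[roi.id] = CellLabel(value, "auto")
    return roiset.labels


def override_label(roiset: ROISet, roi_id: int, value: str) -> dict:
    """Manually set a label; manual labels survive later auto classification."""
    roiset[roi_id]  # raises KeyError for unknown ids
    roiset.labels[roi_id] = CellLabel(value, "manual")
    return roiset.labels


def export_cell_images(session, roiset: ROISet, directory,
                       ref_green: ReferenceImage | None = None,
                       ref_red: ReferenceImage | None = None) -> Path:
    """Write one bounding-box crop per ROI plus a manifest CSV.

    Crops are taken from the reference images (both channels when present)
    and stacked along the last axis; files are named
    ``<session>_<roiID>.tif``. Returns the manifest path.
    """
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = Path(session.source_path).stem or "session"
    manifest = directory / f"{base}_manifest.csv"
    rows = []
    for roi in roiset:
        r0, c0, r1, c1 = roi.bbox
        planes = []
        if ref_green is not None:
            planes.append(np.asarray(ref_green.pixels)[r0:r1, c0:c1])
        if ref_red is not None:
            planes.append(np.asarray(ref_red.pixels)[r0:r1, c0:c1])
        if not planes:
            for c in range(session.n_channels):
                planes.append(session.stack[:, r0:r1, c0:c1, c].mean(axis=0))
        crop = np.stack(planes, axis=-1).astype(np.float32)
        fname = f"{base}_{roi.id}.tif"
        tifffile.imwrite(directory / fname, crop)
        lab = roiset.labels.get(roi.id)
        rows.append({"roi_id": roi.id, "file": fname,
                     "label": lab.value if lab else "", "area": roi.area})
    with open(manifest, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["roi_id", "file", "label", "area"])
        w.writeheader()
        w.writerows(rows)
    return manifest


def import_annotations(roiset: ROISet, path) -> dict:
    """Read a ``roi_id,label`` CSV and apply labels with origin ``imported``.

    Ids absent from the ROI set abort the import (no partial application)
    with every unmatched id named in the error.
    """
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "roi_id" not in reader.fieldnames:
            raise AnnotationImportError(f"{path} is not a roi_id,label CSV")
        for row in reader:
            entries.append((int(row["roi_id"]), row["label"].strip()))
    known = set(roiset.ids)
    unmatched = sorted({rid for rid, _ in entries} - known)
    if unmatched:
        raise AnnotationImportError(f"annotation ids not in ROI set: {unmatched}")
    for rid, value in entries:
        if value not in LABEL_VALUES:
            warnings.warn(f"skipping unknown label {value!r} for ROI {rid}")
            continue
        roiset.labels[rid] = CellLabel(value, "imported")
    return roiset.labels
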