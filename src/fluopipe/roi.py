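"""Reference images, thresholding and ROI extraction.

A reference image is a per-pixel reduction of a chosen frame range of the
movie (average / max / standard deviation), or an externally supplied image.
Thresholding the reference yields a binary mask from which connected
components are extracted as candidate ROIs, filtered by area, and — for
line-scan sessions — mapped onto the scan path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage import measure

__all__ = [
    "ReferenceImage",
    "ROI",
    "ROISet",
    "ThresholdResult",
    "make_reference",
    "threshold_reference",
    "extract_rois",
    "map_rois_to_linescan",
]


@dataclass
class ReferenceImage:
    """A 2-D reference image and the recipe that produced it."""

    pixels: np.ndarray
    method: str  # average | max | std | external
    frames_used: tuple[int, int] | None = None  # half-open range
    channel: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("reference image must be 2-D")
        if self.method == "std" and np.any(self.pixels < 0):
            raise ValueError("std reference must be non-negative")


@dataclass
class ROI:
    """One labelled region: pixel set plus derived geometry.

    ``coords`` is an (N, 2) array of (row, col) pixel coordinates.
    ``eccentricity`` is that of the ellipse with identical second central
    moments (0 = circle, -> 1 = line), the standard regionprops definition.
    """

    id: int
    coords: np.ndarray
    centroid: tuple[float, float]
    eccentricity: float
    bbox: tuple[int, int, int, int]
    line_pixel_indices: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def area(self) -> int:
        return len(self.coords)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        if self.area:
            m[self.coords[:, 0], self.coords[:, 1]] = True
        return m

    def __eq__(self, other):
        if not isinstance(other, ROI):
            return NotImplemented
        return (
            self.id == other.id
            and np.array_equal(self.coords, other.coords)
            and self.flags == other.flags
            and _opt_array_equal(self.line_pixel_indices, other.line_pixel_indices)
        )


def _opt_array_equal(a, b):
    if a is None or b is None:
        return (a is None) == (b is None)
    return np.array_equal(a, b)


@dataclass
class ROISet:
    """Labelled regions over one field of view.

    ``label_image`` holds 0 for background and k for ROI k; the per-ROI
    records in ``rois`` are kept consistent with it (labels are consecutive
    positive integers in raster order of each region's first pixel, the
    ordering ``skimage.measure.label`` produces). ``labels`` maps ROI id to
    its cell-type label once classification has run.
    """

    label_image: np.ndarray
    rois: list[ROI] = field(default_factory=list)
    labels: dict = field(default_factory=dict)  # roi id -> CellLabel

    def __post_init__(self):
        ids = [r.id for r in self.rois]
        present = sorted(set(np.unique(self.label_image)) - {0})
        if sorted(ids) != [int(v) for v in present]:
            raise ValueError("ROI records inconsistent with label image")

    @classmethod
    def from_label_image(cls, label_image: np.ndarray, labels=None) -> "ROISet":
        label_image = np.asarray(label_image)
        rois = []
        for p in measure.regionprops(label_image):
            rois.append(
                ROI(
                    id=int(p.label),
                    coords=np.asarray(p.coords, dtype=np.int64),
                    centroid=tuple(float(c) for c in p.centroid),
                    eccentricity=float(p.eccentricity),
                    bbox=tuple(int(b) for b in p.bbox),
                )
            )
        return cls(label_image=label_image, rois=rois, labels=dict(labels or {}))

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, roi_id: int) -> ROI:
        for r in self.rois:
            if r.id == roi_id:
                return r
        raise KeyError(f"no ROI with id {roi_id}")

    @property
    def ids(self):
        return [r.id for r in self.rois]

    def mask(self) -> np.ndarray:
        """Union of all ROI pixels."""
        return self.label_image > 0

    def __eq__(self, other):
        if not isinstance(other, ROISet):
            return NotImplemented
        return (
            np.array_equal(self.label_image, other.label_image)
            and self.rois == other.rois
            and self.labels == other.labels
        )


def make_reference(session, frames=None, method="average", channel="green") -> ReferenceImage:
    """Reduce a frame range of the movie to a single reference image.

    Parameters
    ----------
    session : ImagingSession
    frames : (start, stop) half-open frame range, or None for all frames.
    method : 'average' | 'max' | 'std'
    channel : channel role name ('green' or 'red').
    """
    if frames is None:
        frames = (0, session.n_frames)
    start, stop = int(frames[0]), int(frames[1])
    if not (0 <= start < stop <= session.n_frames):
        raise ValueError(f"empty or out-of-range frame range {frames!r}")
    c = session.channel_index(channel)
    sub = session.stack[start:stop, :, :, c].astype(np.float64)
    reducers = {"average": np.mean, "max": np.max, "std": np.std}
    if method not in reducers:
        raise ValueError(f"unknown reference method {method!r}")
    pixels = reducers[method](sub, axis=0)
    if session.scan_mode == "line":
        # line-scan movies have no 2-D field of view to reduce
        raise ValueError("reference images are built from frame-scan movies; "
                         "load an external reference for line-scan sessions")
    return ReferenceImage(pixels=pixels, method=method, frames_used=(start, stop), channel=channel)


def load_external_reference(pixels: np.ndarray, session=None) -> ReferenceImage:
    """Wrap an externally produced image as a reference, checking dimensions."""
    pixels = np.asarray(pixels)
    if session is not None and pixels.shape != (session.height, session.width):
        raise ValueError(
            f"external reference shape {pixels.shape} does not match "
            f"session ({session.height}, {session.width})"
        )
    return ReferenceImage(pixels=pixels, method="external")


def _otsu_plateau(img: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold, resolved to the midpoint of the optimal plateau.

    On a cleanly bimodal image every threshold in the empty gap between
    the modes maximises the between-class variance, so picking the first
    maximising bin (the common library convention) lands just above the
    background mode; the plateau midpoint is the stable choice.
    """
    counts, edges = np.histogram(img.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts).astype(np.float64)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    mu0 = np.divide(m, w0, out=np.zeros_like(m), where=w0 > 0)
    mu1 = np.divide(m[-1] - m, w1, out=np.zeros_like(m), where=w1 > 0)
    var_b = w0 * w1 * (mu0 - mu1) ** 2
    best = var_b.max()
    plateau = set(np.nonzero(var_b >= best * (1 - 1e-12))[0].tolist())
    # contiguous run containing the first maximum
    i0 = min(plateau)
    i1 = i0
    while i1 + 1 in plateau:
        i1 += 1
    return float(edges[(i0 + i1) // 2 + 1])


@dataclass
class ThresholdResult:
    """Binary mask plus the threshold actually applied (for reports)."""

    mask: np.ndarray
    threshold: float
    method: str

    def __array__(self, dtype=None):
        return self.mask.astype(dtype) if dtype else self.mask


def threshold_reference(ref: ReferenceImage, method="otsu", value=None) -> ThresholdResult:
    """Threshold a reference image into a binary mask (pixel >= threshold).

    method 'otsu' needs no value; 'fraction_of_max' takes value in (0, 1);
    'absolute' takes an intensity. A flat image under Otsu, or an absolute
    threshold above the image maximum, yields an empty mask with a warning
    rather than an error.
    """
    img = np.asarray(ref.pixels, dtype=np.float64)
    if method == "otsu":
        if np.ptp(img) == 0:
            warnings.warn("flat reference image: Otsu threshold undefined, empty mask returned")
            return ThresholdResult(np.zeros(img.shape, dtype=bool), np.inf, method)
        thr = _otsu_plateau(img)
        return ThresholdResult(img >= thr, thr, method)
    if method == "fraction_of_max":
        if value is None or not (0 < value < 1):
            raise ValueError("fraction_of_max requires 0 < value < 1")
        thr = float(value) * float(img.max())
    elif method == "absolute":
        if value is None:
            raise ValueError("absolute threshold requires a value")
        thr = float(value)
        if thr > img.max():
            warnings.warn(f"absolute threshold {thr} above image max {img.max()}: empty mask")
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdResult(img >= thr, thr, method)


def extract_rois(mask, min_area: int = 1, max_area: int | None = None) -> ROISet:
    """Connected components (8-connectivity) of a mask, filtered by area.

    Components with area < ``min_area`` or > ``max_area`` are dropped; the
    survivors are relabelled 1..K in raster order of their first pixel.
    An empty mask yields an empty ROISet.
    """
    if isinstance(mask, ThresholdResult):
        mask = mask.mask
    mask = np.asarray(mask, dtype=bool)
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    if max_area is not None and max_area < min_area:
        raise ValueError("max_area must be >= min_area")
    lab = measure.label(mask, connectivity=2)
    keep = np.zeros(lab.max() + 1, dtype=np.int32)
    next_id = 1
    for p in measure.regionprops(lab):
        if p.area < min_area or (max_area is not None and p.area > max_area):
            continue
        keep[p.label] = next_id
        next_id += 1
    relabelled = keep[lab]
    return ROISet.from_label_image(relabelled)


def map_rois_to_linescan(roiset: ROISet, line_path, min_line_pixels: int = 3) -> ROISet:
    """Annotate each ROI with the scan-path indices falling inside it.

    ROIs represented by fewer than ``min_line_pixels`` path pixels are
    removed (survivors are relabelled consecutively). The default of 3
    rejects grazing intersections while keeping usable traces.
    """
    if line_path is None or len(line_path) == 0:
        raise ValueError("session has no line path (not a line-scan session)")
    path = np.asarray(line_path, dtype=np.int64)
    h, w = roiset.label_image.shape
    if path[:, 0].max() >= h or path[:, 1].max() >= w or path.min() < 0:
        raise ValueError("line path coordinates outside the reference image")
    path_labels = roiset.label_image[path[:, 0], path[:, 1]]
    new_label = np.zeros(roiset.label_image.max() + 1, dtype=np.int32)
    kept = []
    next_id = 1
    for r in roiset.rois:
        idx = np.nonzero(path_labels == r.id)[0]
        if len(idx) < min_line_pixels:
            continue
        new_label[r.id] = next_id
        kept.append(replace(r, id=next_id, line_pixel_indices=idx.astype(np.int64)))
        next_id += 1
    label_image = new_label[roiset.label_image]
    labels = {}
    for old_id, lab_val in roiset.labels.items():
        if new_label[old_id]:
            labels[int(new_label[old_id])] = lab_val
    return ROISet(label_image=label_image, rois=kept, labels=labels)
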