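"""Nuclei and cell-body segmentation from multi-channel z-stack fields.

The operator sequence is: maximum-intensity projection of the Hoechst
z-stack, Gaussian smoothing, global thresholding, optional
distance-transform watershed splitting, size filtering. Cell bodies are
obtained from a bright-field (or digital phase contrast) image and
partitioned among nuclei with a seeded watershed so that every retained
body contains exactly one nucleus object.

Coordinates are 0-based pixel indices with origin at the top-left;
``(x, y)`` means ``(column, row)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed


class SegmentationError(ValueError):
    """Raised for invalid segmentation inputs (shape/stack errors)."""


@dataclass
class ImageField:
    """One imaged field: per-channel z-stacks plus acquisition metadata.

    Parameters
    ----------
    channels
        Mapping channel-id -> z-stack, each an array of shape (z, y, x).
        All channels must share shape and z-count.
    pixel_depth
        Bit depth of the acquisition (8 or 16 typically).
    metadata
        Free-form dict; conventional keys: ``well``, ``field``,
        ``timepoint`` (hours), ``cell_line``, ``mode``.
    """

    channels: dict[str, np.ndarray]
    pixel_depth: int = 16
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.channels.items()}
        if shapes:
            ref = next(iter(shapes.values()))
            bad = {k: s for k, s in shapes.items() if s != ref}
            if bad:
                raise SegmentationError(
                    f"channel shape mismatch: expected {ref}, got {bad}"
                )
            for k, v in self.channels.items():
                arr = np.asarray(v)
                if arr.ndim != 3:
                    raise SegmentationError(
                        f"channel {k!r} must be a (z, y, x) stack, got ndim={arr.ndim}"
                    )
                if np.any(arr < 0):
                    raise SegmentationError(f"channel {k!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        stack = next(iter(self.channels.values()))
        return np.asarray(stack).shape[1:]

    def projection(self, channel: str) -> np.ndarray:
        return project_stack(self.channels[channel])


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k > 0 = object k.

    Labels are consecutive ``1..K``. ``provenance`` records which
    segmentation stage produced the mask; ``notes`` carries per-label
    annotations (e.g. fallback bodies).
    """

    labels: np.ndarray
    provenance: Literal["nuclei", "cell_body"]
    notes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise SegmentationError("label mask must be 2-D")
        if lab.min() < 0:
            raise SegmentationError("label mask has negative labels")
        present = np.unique(lab)
        present = present[present > 0]
        if present.size and not np.array_equal(present, np.arange(1, present.size + 1)):
            raise SegmentationError("labels must be consecutive 1..K")
        self.labels = lab

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def centroids(self) -> np.ndarray:
        """(K, 2) array of (x, y) centroids ordered by label."""
        props = regionprops(self.labels)
        return np.array([(p.centroid[1], p.centroid[0]) for p in props])


@dataclass
class SegmentationParams:
    smooth_sigma: float = 2.0
    threshold_method: Literal["otsu", "quantile"] = "otsu"
    threshold_quantile: float = 0.95
    threshold_clip_percentile: float = 99.0
    min_area: float = 30.0
    max_area: float = 5000.0
    split_touching: bool = True
    split_min_distance: int = 10
    exclude_border: bool = False
    # cell-body parameters
    body_fallback_radius: int = 12
    body_min_area: float = 20.0


def project_stack(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection of a (z, y, x) stack onto (y, x)."""
    arr = np.asarray(stack)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] < 1 or arr.size == 0:
        raise SegmentationError("projection requires a non-empty (z, y, x) stack")
    return arr.max(axis=0)


def digital_phase_contrast(
    stack: np.ndarray,
    z_lo: int = 3,
    z_hi: int = 5,
    level: float = 0.003,
    one_based: bool = True,
) -> np.ndarray:
    """Contrast image from two focal planes of a bright-field stack.

    Computed as the normalized absolute difference between the
    above-focus and below-focus slices,
    ``|I_hi - I_lo| / (I_hi + I_lo)``, with values below ``level`` set
    to zero. Defaults use slices 3 and 5 (1-based) at level 0.003.
    """
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise SegmentationError("digital phase contrast requires a (z, y, x) stack")
    if level <= 0:
        raise SegmentationError("level must be > 0")
    lo, hi = (z_lo - 1, z_hi - 1) if one_based else (z_lo, z_hi)
    if not (0 <= lo < hi < arr.shape[0]):
        raise SegmentationError(
            f"slice indices out of range: z_lo={z_lo}, z_hi={z_hi} for {arr.shape[0]} slices"
        )
    a, b = arr[hi], arr[lo]
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        contrast = np.abs(a - b) / denom
    contrast[denom == 0] = 0.0
    contrast[contrast < level] = 0.0
    return contrast


def _threshold(img: np.ndarray, params: SegmentationParams) -> float:
    if params.threshold_method == "otsu":
        # rare extreme outliers (precipitates, saturated artifacts) can
        # pull Otsu's split above the nuclei; exclude the top tail from
        # the histogram (affine-equivariant, so intensity-rescaling
        # invariance is preserved)
        clipped = img[img <= np.percentile(img, params.threshold_clip_percentile)]
        if clipped.size and clipped.max() > clipped.min():
            return float(threshold_otsu(clipped))
        return float(threshold_otsu(img))
    return float(np.quantile(img, params.threshold_quantile))


def _relabel(lab: np.ndarray) -> np.ndarray:
    """Relabel to consecutive 1..K preserving raster order of first pixels."""
    out, _, _ = _relabel_with_map(lab)
    return out


def _relabel_with_map(lab: np.ndarray):
    present = np.unique(lab)
    present = present[present > 0]
    lut = np.zeros(int(lab.max()) + 1, dtype=np.int32)
    fwd: dict[int, int] = {}
    for new, old in enumerate(present, start=1):
        lut[old] = new
        fwd[int(old)] = new
    return lut[lab], fwd, present


def segment_nuclei(
    hoechst_projection: np.ndarray,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Detect nuclei: smooth -> threshold -> label -> split -> size filter.

    A blank (constant) image yields an empty mask rather than an error.
    Objects touching the image border are retained unless
    ``params.exclude_border``. Fragmented nuclei deliberately remain
    separate objects; grouping into cells happens at feature time.
    """
    params = params or SegmentationParams()
    img = np.asarray(hoechst_projection, dtype=float)
    if img.ndim != 2:
        raise SegmentationError("expected a 2-D projection")
    empty = LabelMask(np.zeros(img.shape, dtype=np.int32), "nuclei")
    if img.size == 0 or img.max() == img.min():
        return empty

    smoothed = gaussian(img, sigma=params.smooth_sigma, preserve_range=True)
    thr = _threshold(smoothed, params)
    binary = smoothed > thr
    if not binary.any():
        return empty

    lab = cc_label(binary)
    if params.split_touching:
        dist = ndi.distance_transform_edt(binary)
        peaks = peak_local_max(
            dist,
            min_distance=params.split_min_distance,
            labels=lab,
            exclude_border=False,
        )
        if len(peaks):
            markers = np.zeros(binary.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            lab = watershed(-dist, markers=markers, mask=binary)

    # size filter
    sizes = np.bincount(lab.ravel())
    keep = (sizes >= params.min_area) & (sizes <= params.max_area)
    keep[0] = False
    lab = np.where(keep[lab], lab, 0)

    if params.exclude_border:
        border_labels = np.unique(
            np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
        )
        lab = np.where(np.isin(lab, border_labels[border_labels > 0]), 0, lab)

    return LabelMask(_relabel(lab).astype(np.int32), "nuclei")


def segment_cell_bodies(
    intensity_image: np.ndarray,
    nuclei: LabelMask,
    params: SegmentationParams | None = None,
) -> LabelMask:
    """Partition cell-body foreground among nuclei by seeded watershed.

    ``intensity_image`` is a bright-field projection or a digital phase
    contrast image. Foreground is the Otsu threshold of the absolute
    deviation from the image median (robust to bright-on-dark or
    dark-on-bright cells). Each body contains exactly one nucleus
    object; nuclei with no foreground support receive a disk fallback
    body (annotated ``"fallback"`` in the mask notes).
    """
    params = params or SegmentationParams()
    img = np.asarray(intensity_image, dtype=float)
    if img.shape != nuclei.labels.shape:
        raise SegmentationError(
            f"intensity image shape {img.shape} != nuclei mask shape {nuclei.labels.shape}"
        )
    nuc = nuclei.labels
    if nuclei.n_objects == 0:
        return LabelMask(np.zeros(img.shape, dtype=np.int32), "cell_body")

    dev = np.abs(img - np.median(img))
    if dev.max() > 0:
        thr = threshold_otsu(dev)
        fg = dev > thr
    else:
        fg = np.zeros(img.shape, dtype=bool)
    fg |= nuc > 0

    # geodesic-ish partition: flood from nucleus seeds ordered by
    # Euclidean distance to the nearest nucleus pixel
    dist_to_nuc = ndi.distance_transform_edt(nuc == 0)
    bodies = watershed(dist_to_nuc, markers=nuc, mask=fg)

    notes: dict[int, str] = {}
    selem = disk(params.body_fallback_radius)
    for lbl in range(1, nuclei.n_objects + 1):
        nuc_mask = nuc == lbl
        body_mask = bodies == lbl
        if body_mask.sum() <= nuc_mask.sum() * 1.2:
            # no cytoplasmic support: stamp a disk around the centroid
            cy, cx = ndi.center_of_mass(nuc_mask)
            rr = np.zeros(img.shape, dtype=bool)
            r = params.body_fallback_radius
            y0, y1 = int(cy) - r, int(cy) + r + 1
            x0, x1 = int(cx) - r, int(cx) + r + 1
            sy0, sy1 = max(0, y0), min(img.shape[0], y1)
            sx0, sx1 = max(0, x0), min(img.shape[1], x1)
            rr[sy0:sy1, sx0:sx1] = selem[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] > 0
            claim = rr & (bodies == 0)
            bodies[claim] = lbl
            bodies[nuc_mask] = lbl
            notes[lbl] = "fallback"

    relabeled, fwd, _ = _relabel_with_map(bodies)
    notes = {fwd[k]: v for k, v in notes.items() if k in fwd}
    return LabelMask(relabeled.astype(np.int32), "cell_body", notes=notes)
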