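"""Label-free cell detection in phase-contrast time-lapse stacks.

Per-frame chain: translation drift correction, Gaussian-weighted local
variance to lift textured cells off the homogeneous background, Otsu
binarization with hole filling, an inverted difference-of-Gaussians
landscape whose minima sit at cell centers, extended (h-)minima as seeds,
marker-controlled watershed restricted to sub-cluster-sized foreground
components, and finally size-based classing: objects below ``min_area``
are noise, up to ``cluster_area`` are single cells, and anything at or
above that is a cell cluster left unsplit (watershed output on dense
clumps is unreliable, so clusters are tracked as single objects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import local_minima, reconstruction
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

__all__ = [
    "ImageStack",
    "LabelStack",
    "SegmentationParams",
    "estimate_drift",
    "correct_drift",
    "local_variance",
    "foreground_mask",
    "dog_landscape",
    "extended_minima_markers",
    "split_and_label",
    "classify_objects",
    "segment_frame",
    "segment_stack",
]

CELL, CLUSTER = "cell", "cluster"

OBJECT_COLUMNS = ["frame", "label", "area_px2", "x", "y", "class"]


@dataclass
class ImageStack:
    """Time-lapse grayscale frames (T x H x W) with acquisition interval."""

    frames: np.ndarray
    frame_interval: float = 20.0  # minutes between frames

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"expected T x H x W array, got shape {self.frames.shape}")
        if not np.isfinite(self.frames).all():
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape[1:]


@dataclass
class LabelStack:
    """Per-frame labeled objects and their table (frame, label, area, centroid, class)."""

    labels: np.ndarray
    object_table: pd.DataFrame

    def frame_counts(self, cls: str = CELL) -> pd.Series:
        t = self.object_table
        return t[t["class"] == cls].groupby("frame").size()


@dataclass
class SegmentationParams:
    variance_sigma: float = 5.0  # px, local-variance window
    dog_sigma: float = 7.0  # px, wide DoG scale
    dog_sigma_low: float = 1.0  # px, narrow DoG scale
    minima_depth_h: int = 10  # 8-bit units, extended-minima depth
    connectivity: int = 8  # 4 or 8
    min_area: float = 200.0  # px^2, below = noise
    cluster_area: float = 2000.0  # px^2, at/above = cluster

    def __post_init__(self) -> None:
        if not 0 < self.dog_sigma_low < self.dog_sigma:
            raise ValueError("require 0 < dog_sigma_low < dog_sigma")
        if not self.min_area < self.cluster_area:
            raise ValueError("require min_area < cluster_area")
        if not 0 < self.minima_depth_h <= 255:
            raise ValueError("minima_depth_h must lie in (0, 255]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _skimage_connectivity(self) -> int:
        # skimage counts connectivity in orthogonal steps: 1 = 4-conn, 2 = 8-conn
        return 1 if self.connectivity == 4 else 2


def estimate_drift(stack: ImageStack, upsample_factor: int = 20) -> np.ndarray:
    """Per-frame (dx, dy) translation of each frame relative to frame 0.

    Subpixel phase cross-correlation; positive dx means frame content
    moved right relative to the reference.  Blank (zero-variance) frames
    get a zero shift with a warning.
    """
    if stack.n_frames < 2:
        raise ValueError("drift estimation needs at least 2 frames")
    ref = stack.frames[0].astype(float)
    drifts = np.zeros((stack.n_frames, 2))
    ref_flat = ref.std() == 0
    for t in range(1, stack.n_frames):
        cur = stack.frames[t].astype(float)
        if ref_flat or cur.std() == 0:
            warnings.warn(f"frame {t} (or reference) is blank; drift set to 0", stacklevel=2)
            continue
        shift, _, _ = phase_cross_correlation(ref, cur, upsample_factor=upsample_factor)
        # shift = (rows, cols) to apply to the frame to register it onto ref
        drifts[t] = (-shift[1], -shift[0])
    return drifts


def correct_drift(stack: ImageStack, drifts: np.ndarray) -> ImageStack:
    """Shift each frame by the negated drift, aligning all frames to frame 0."""
    out = np.empty_like(stack.frames, dtype=float)
    for t in range(stack.n_frames):
        dx, dy = drifts[t]
        if dx == 0 and dy == 0:
            out[t] = stack.frames[t]
        else:
            out[t] = ndi.shift(
                stack.frames[t].astype(float), (-dy, -dx), order=1, mode="nearest"
            )
    return ImageStack(frames=out, frame_interval=stack.frame_interval)


def local_variance(frame: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian-weighted local variance: E[x^2] - E[x]^2 under a Gaussian window."""
    f = frame.astype(float)
    m = ndi.gaussian_filter(f, sigma)
    m2 = ndi.gaussian_filter(f * f, sigma)
    return np.clip(m2 - m * m, 0, None)


def foreground_mask(frame: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Variance filter -> Otsu threshold -> hole fill; True marks cells.

    A constant frame has no Otsu threshold; the mask is empty and a
    warning is emitted.
    """
    params = params or SegmentationParams()
    var = local_variance(frame, params.variance_sigma)
    if var.max() == var.min():
        warnings.warn("constant frame: empty foreground mask", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    mask = var > threshold_otsu(var)
    return ndi.binary_fill_holes(mask)


def dog_landscape(frame: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Inverted difference-of-Gaussians rescaled to the full 8-bit range.

    Bright blob interiors become landscape minima, suitable for seeding a
    watershed.  A constant frame yields a constant zero landscape.
    """
    params = params or SegmentationParams()
    f = frame.astype(float)
    dog = ndi.gaussian_filter(f, params.dog_sigma_low) - ndi.gaussian_filter(
        f, params.dog_sigma
    )
    inv = -dog
    lo, hi = inv.min(), inv.max()
    if hi == lo:
        warnings.warn("constant frame: constant landscape", stacklevel=2)
        return np.zeros(frame.shape, dtype=np.uint8)
    return np.round((inv - lo) * (255.0 / (hi - lo))).astype(np.uint8)


def extended_minima_markers(
    landscape: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Label the extended minima (depth >= h) of the landscape as seed markers.

    Classical definition: regional minima of the h-minima transform
    (reconstruction by erosion of ``landscape + h`` over ``landscape``),
    so basins separated by ridges shallower than h merge into one marker.
    """
    params = params or SegmentationParams()
    f = landscape.astype(np.int16)
    filled = reconstruction(f + params.minima_depth_h, f, method="erosion")
    minima = local_minima(filled, connectivity=params._skimage_connectivity)
    return cc_label(minima, connectivity=params._skimage_connectivity)


def split_and_label(
    mask: np.ndarray,
    markers: np.ndarray,
    landscape: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Watershed-split sub-cluster foreground components; relabel everything.

    Components with area < ``cluster_area`` are flooded from the markers
    they contain (split restricted to the component); components at or
    above ``cluster_area``, or containing no marker, pass through whole.
    The union of foreground pixels is never changed.
    """
    params = params or SegmentationParams()
    conn = params._skimage_connectivity
    components = cc_label(mask, connectivity=conn)
    out = np.zeros(mask.shape, dtype=np.int32)
    next_label = 1
    for region in regionprops(components):
        comp = components == region.label
        pieces = None
        if region.area < params.cluster_area:
            local_markers = np.where(comp, markers, 0)
            if local_markers.any():
                ws = watershed(landscape, markers=local_markers, mask=comp)
                ids = np.unique(ws)
                pieces = [ws == i for i in ids if i != 0]
        if pieces is None:
            pieces = [comp]
        for piece in pieces:
            out[piece] = next_label
            next_label += 1
    return out


def classify_objects(
    label_map: np.ndarray, params: SegmentationParams | None = None, frame: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop sub-``min_area`` noise and class the rest as cell or cluster.

    Area thresholds are inclusive on the low side of each class: exactly
    ``min_area`` px^2 is a cell, exactly ``cluster_area`` px^2 a cluster.
    Centroids are mean pixel coordinates (x = column, y = row).
    """
    params = params or SegmentationParams()
    rows = []
    cleaned = np.zeros_like(label_map, dtype=np.int32)
    next_label = 1
    for region in regionprops(label_map):
        if region.area < params.min_area:
            continue
        cls = CLUSTER if region.area >= params.cluster_area else CELL
        cy, cx = region.centroid
        cleaned[label_map == region.label] = next_label
        rows.append(
            {
                "frame": frame,
                "label": next_label,
                "area_px2": float(region.area),
                "x": float(cx),
                "y": float(cy),
                "class": cls,
            }
        )
        next_label += 1
    table = pd.DataFrame(rows, columns=OBJECT_COLUMNS)
    return cleaned, table


def segment_frame(
    frame: np.ndarray, params: SegmentationParams | None = None, frame_index: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Full single-frame chain: mask -> landscape -> markers -> split -> classify."""
    params = params or SegmentationParams()
    mask = foreground_mask(frame, params)
    landscape = dog_landscape(frame, params)
    markers = extended_minima_markers(landscape, params)
    labels = split_and_label(mask, markers, landscape, params)
    return classify_objects(labels, params, frame=frame_index)


def segment_stack(
    stack: ImageStack,
    params: SegmentationParams | None = None,
    correct_drift_first: bool = True,
) -> LabelStack:
    """Segment every frame of a (drift-corrected) stack into a LabelStack."""
    params = params or SegmentationParams()
    if correct_drift_first and stack.n_frames >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            drifts = estimate_drift(stack)
        stack = correct_drift(stack, drifts)
    all_labels = np.zeros(stack.frames.shape, dtype=np.int32)
    tables = []
    for t in range(stack.n_frames):
        try:
            labels, table = segment_frame(stack.frames[t], params, frame_index=t)
        except Exception as exc:  # annotate failures with the frame index
            raise RuntimeError(f"segmentation failed at frame {t}: {exc}") from exc
        all_labels[t] = labels
        tables.append(table)
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=OBJECT_COLUMNS)
    )
    return LabelStack(labels=all_labels, object_table=table)
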