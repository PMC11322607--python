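"""Per-z-plane object detection, tumoroid boundary masks and T-cell masking.

Follows the classic per-plane pipeline of the assay readout: identify
primary objects in each channel of every z-section, build a tumoroid
boundary mask from the nuclei channel, and discard T-cells whose centroid
falls outside that boundary. The boundary is constructed with a standard
smoothed-threshold / morphological-closing / hole-filling procedure; the
watershed split of touching nuclei uses the distance transform of the
thresholded plane.

Conventions: pixel indices are 0-based; physical coordinates are
pixel-center µm (`x_um = (col + 0.5) * pixel_size`); all outputs are in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import closing as _closing, disk
from skimage.segmentation import watershed

from tumotrack.scenario import ValidationError


@dataclass(frozen=True)
class Plane:
    """One calibrated z-section of one channel at one timepoint."""

    intensity: np.ndarray      # (Y, X), non-negative
    channel: str               # "nuclei" | "pi" | "tcell"
    z: int
    t: int
    pixel_size: float          # µm / px

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be > 0")
        if self.intensity.ndim != 2:
            raise ValidationError("plane intensity must be 2D")


@dataclass
class PlaneObjects:
    """Labeled 2D objects of one class in one plane.

    ``labels`` is a (Y, X) grid with 0 = background and objects numbered
    1..n in raster order of their topmost-leftmost pixel; ``table`` holds
    one row per object: label, centroid (µm) and area (µm²).
    """

    labels: np.ndarray
    table: pd.DataFrame        # columns: label, x_um, y_um, area_um2
    channel: str
    z: int = 0
    t: int = 0
    pixel_size: float = 1.0

    @property
    def count(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class SegmentationParams:
    """Smoothing, threshold and size-filter settings for one channel.

    ``threshold`` is "otsu" (per plane) or a fixed global intensity value;
    a fixed value gives reproducible behavior across sparse planes where
    Otsu would track noise. Areas are physical (µm²).
    """

    smoothing_sigma_um: float = 2.0
    threshold: float | str = "otsu"
    min_area_um2: float = 10.0
    max_area_um2: float = 10_000.0
    split_touching: bool = True
    split_min_distance_um: float = 5.0

    def __post_init__(self) -> None:
        if self.min_area_um2 < 0 or self.max_area_um2 <= self.min_area_um2:
            raise ValidationError("area bounds must satisfy 0 <= min < max")
        if self.smoothing_sigma_um < 0:
            raise ValidationError("smoothing sigma must be >= 0")


@dataclass
class TumoroidMask:
    """Binary tumoroid footprint per z-plane (True = inside boundary)."""

    masks: Dict[int, np.ndarray] = field(default_factory=dict)  # z -> (Y, X) bool
    pixel_size: float = 1.0

    def area_um2(self, z: int) -> float:
        mask = self.masks.get(z)
        return 0.0 if mask is None else float(mask.sum()) * self.pixel_size ** 2

    def plane(self, z: int, shape: Tuple[int, int] | None = None) -> np.ndarray:
        mask = self.masks.get(z)
        if mask is None:
            if shape is None:
                raise ValidationError(f"no mask stored for z={z} and no shape given")
            return np.zeros(shape, dtype=bool)
        return mask


def _raster_relabel(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..n in raster order of first occurrence, so output
    labeling is deterministic regardless of intermediate ordering."""
    flat = labels.ravel()
    out = np.zeros_like(labels)
    mapping: Dict[int, int] = {}
    next_label = 1
    for value in flat:
        if value and value not in mapping:
            mapping[value] = next_label
            next_label += 1
    if mapping:
        lut = np.zeros(labels.max() + 1, dtype=labels.dtype)
        for old, new in mapping.items():
            lut[old] = new
        out = lut[labels]
    return out


def segment_objects(plane: Plane, params: SegmentationParams | None = None
                    ) -> PlaneObjects:
    """Identify primary objects in one plane.

    Gaussian smoothing → global threshold (Otsu per plane by default, or a
    fixed value) → optional distance-transform watershed split of touching
    objects → area filter. Constant planes yield zero objects.
    """
    params = params or SegmentationParams()
    img = np.asarray(plane.intensity, dtype=float)
    px = plane.pixel_size
    if params.smoothing_sigma_um > 0:
        img = gaussian(img, sigma=params.smoothing_sigma_um / px,
                       preserve_range=True)
    if np.ptp(img) <= 1e-9 * (abs(float(img.max())) + 1.0):
        return _empty_objects(plane)  # constant plane: nothing to segment
    if params.threshold == "otsu":
        if img.max() == img.min():
            return _empty_objects(plane)
        thr = float(threshold_otsu(img))
    else:
        thr = float(params.threshold)
    mask = img > thr
    if not mask.any():
        return _empty_objects(plane)
    if params.split_touching:
        distance = ndimage.distance_transform_edt(mask)
        min_dist_px = max(1, int(round(params.split_min_distance_um / px)))
        peaks = peak_local_max(distance, min_distance=min_dist_px,
                               labels=mask, exclude_border=False)
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels, _ = ndimage.label(mask)
        else:
            labels = watershed(-distance, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)
    # area filter in physical units
    px_area = px ** 2
    counts = np.bincount(labels.ravel())
    for label_value in range(1, len(counts)):
        area = counts[label_value] * px_area
        if not params.min_area_um2 <= area <= params.max_area_um2:
            labels[labels == label_value] = 0
    labels = _raster_relabel(labels)
    rows = []
    for prop in regionprops(labels, intensity_image=img):
        cy, cx = prop.centroid_weighted if prop.intensity_max > 0 else prop.centroid
        rows.append((prop.label, (cx + 0.5) * px, (cy + 0.5) * px,
                     prop.area * px_area))
    table = pd.DataFrame(rows, columns=["label", "x_um", "y_um", "area_um2"])
    return PlaneObjects(labels=labels, table=table, channel=plane.channel,
                        z=plane.z, t=plane.t, pixel_size=px)


def _empty_objects(plane: Plane) -> PlaneObjects:
    return PlaneObjects(
        labels=np.zeros(plane.intensity.shape, dtype=np.int32),
        table=pd.DataFrame(columns=["label", "x_um", "y_um", "area_um2"]),
        channel=plane.channel, z=plane.z, t=plane.t,
        pixel_size=plane.pixel_size)


def build_tumoroid_mask(nuclei_by_plane: Dict[int, PlaneObjects],
                        closing_radius_um: float = 20.0,
                        fill_holes: bool = True,
                        convex_hull: bool = True) -> TumoroidMask:
    """Tumoroid boundary from per-plane nucleus objects.

    Per plane: union of nucleus footprints → morphological closing with a
    disk of ``closing_radius_um`` → hole filling → (by default) per-plane
    convex hull. The hull step makes the boundary of a roughly spherical
    tumoroid robust to sparse nucleus sampling, where closing alone leaves
    the cross-section porous. Planes without nuclei get an empty mask.
    Adding a nucleus can only grow the mask: closing, filling and the hull
    are all extensive and monotone in the input union.
    """
    from skimage.morphology import convex_hull_image
    masks: Dict[int, np.ndarray] = {}
    pixel_size = 1.0
    for z, objs in nuclei_by_plane.items():
        pixel_size = objs.pixel_size
        union = objs.labels > 0
        if union.any() and closing_radius_um > 0:
            radius_px = max(1, int(round(closing_radius_um / objs.pixel_size)))
            union = _closing(union, disk(radius_px)).astype(bool)
        if fill_holes and union.any():
            union = ndimage.binary_fill_holes(union)
        if convex_hull and union.any():
            union = convex_hull_image(union)
        masks[z] = union
    return TumoroidMask(masks=masks, pixel_size=pixel_size)


def mask_tcells(tcells: PlaneObjects, mask: TumoroidMask
                ) -> Tuple[PlaneObjects, PlaneObjects]:
    """Partition T-cell objects by the centroid-in-mask rule.

    A T-cell is "inside" iff its centroid pixel is mask-true (boundary
    pixels count as inside). Counts are conserved:
    ``inside.count + outside.count == tcells.count``.
    """
    grid = mask.plane(tcells.z, shape=tcells.labels.shape)
    if grid.shape != tcells.labels.shape:
        raise ValidationError(
            f"mask shape {grid.shape} != plane shape {tcells.labels.shape}")
    inside_rows, outside_rows = [], []
    px = tcells.pixel_size
    for row in tcells.table.itertuples(index=False):
        col = min(grid.shape[1] - 1, max(0, int(row.x_um / px)))
        r = min(grid.shape[0] - 1, max(0, int(row.y_um / px)))
        (inside_rows if grid[r, col] else outside_rows).append(row)
    def _subset(rows: List) -> PlaneObjects:
        table = pd.DataFrame(rows, columns=tcells.table.columns)
        keep = set(table["label"]) if len(table) else set()
        labels = np.where(np.isin(tcells.labels, list(keep)), tcells.labels, 0)
        return PlaneObjects(labels=labels, table=table, channel=tcells.channel,
                            z=tcells.z, t=tcells.t, pixel_size=px)
    return _subset(inside_rows), _subset(outside_rows)
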