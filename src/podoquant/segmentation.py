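"""Nucleus and compartment segmentation within a glomerulus.

All nuclei are segmented from the Hoechst counterstain restricted to the
glomerulus ROI: Gaussian smoothing, Otsu foreground threshold computed from
ROI pixels only, hole filling, then watershed splitting of touching objects
seeded at distance-transform maxima.  Podocyte nuclei are the subset whose
mean p57 intensity exceeds the calibrated positivity threshold (strictly
above).  The NQO1-positive area — the podocyte cytoplasmic compartment — is a
plain pixel threshold on the raw NQO1 channel inside the ROI, with speckle
components below a minimum area removed.

Per-object intensities are always measured on the raw, unsmoothed planes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi
from shapely.geometry import Point
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.segmentation import watershed

from .calibration import ThresholdSet
from .io import CHANNELS, GlomerulusROI, MultiplexImage


@dataclass
class SegmentationParams:
    """Tunable knobs of the nucleus detector.

    Defaults bracket human nuclei at ~0.25 µm/px: smoothing sigma 1.5 px,
    accepted nuclear area 15–120 µm², watershed seeds merged within 3 px.
    """

    smoothing_sigma_px: float = 1.5
    hoechst_threshold_mode: str = "otsu_in_roi"  # or "fixed"
    fixed_hoechst_threshold: float | None = None
    min_nucleus_area_um2: float = 15.0
    max_nucleus_area_um2: float = 120.0
    split_touching: bool = True
    peak_merge_distance_px: float = 3.0
    min_nqo1_component_um2: float = 2.0

    def __post_init__(self) -> None:
        if not self.smoothing_sigma_px > 0:
            raise ValueError("smoothing_sigma_px must be positive")
        if not self.min_nucleus_area_um2 < self.max_nucleus_area_um2:
            raise ValueError("min nucleus area must be below max nucleus area")
        if self.hoechst_threshold_mode not in ("otsu_in_roi", "fixed"):
            raise ValueError(f"unknown threshold mode {self.hoechst_threshold_mode!r}")
        if self.hoechst_threshold_mode == "fixed" and self.fixed_hoechst_threshold is None:
            raise ValueError("fixed threshold mode requires fixed_hoechst_threshold")


@dataclass
class NucleusObject:
    """One segmented nucleus with per-channel mean raw intensities."""

    nucleus_id: int
    mask: np.ndarray  # full-frame boolean mask, clipped to the ROI
    centroid: tuple[float, float]  # (x, y) pixel coordinates
    area_um2: float
    mean_intensity: dict[str, float]
    is_podocyte: bool = False


@dataclass
class CompartmentMask:
    """A marker-defined compartment (the NQO1-positive area) inside one ROI."""

    mask: np.ndarray
    area_um2: float
    channel: str = "nqo1"


def segment_nuclei(
    image: MultiplexImage, roi: GlomerulusROI, params: SegmentationParams | None = None
) -> list[NucleusObject]:
    """Segment all nuclei inside a glomerulus from the Hoechst channel.

    Nuclei straddling the ROI boundary are kept iff their centroid lies inside
    the ring, and their masks are clipped to the ROI interior, so each nucleus
    is counted by exactly one annotation.  Returns an empty list when the ROI
    does not intersect the image or contains no foreground.
    """
    params = params or SegmentationParams()
    roi_mask = roi.mask(image.shape)
    if not roi_mask.any():
        return []

    hoechst = image.plane("hoechst").astype(np.float64)
    smoothed = ndi.gaussian_filter(hoechst, params.smoothing_sigma_px)

    vals = smoothed[roi_mask]
    if params.hoechst_threshold_mode == "fixed":
        thr = float(params.fixed_hoechst_threshold)
    else:
        if np.ptp(vals) == 0:  # flat ROI: nothing to separate
            return []
        thr = float(threshold_otsu(vals))
    fg = roi_mask & (smoothed > thr)
    if not fg.any():
        return []
    fg = ndi.binary_fill_holes(fg)

    if params.split_touching:
        dist = ndi.distance_transform_edt(fg)
        # Smoothing the distance map suppresses plateau artefacts; seeds closer
        # than the merge distance collapse to the brightest (ties resolved
        # deterministically by array order).
        dist_s = ndi.gaussian_filter(dist, 1.0)
        min_dist = max(1, int(round(params.peak_merge_distance_px)))
        peaks = peak_local_max(
            dist_s, min_distance=min_dist, labels=fg, exclude_border=False
        )
        if len(peaks) == 0:
            labels = label(fg)
        else:
            markers = np.zeros(fg.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = watershed(-dist_s, markers, mask=fg)
    else:
        labels = label(fg)

    px_area = image.pixel_size_um**2
    poly = roi.polygon()
    nuclei: list[NucleusObject] = []
    nucleus_id = 0
    for region in regionprops(labels):
        area_um2 = region.area * px_area
        if not params.min_nucleus_area_um2 <= area_um2 <= params.max_nucleus_area_um2:
            continue
        cy, cx = region.centroid  # (row, col)
        if not poly.contains(Point(cx, cy)):
            continue
        mask = labels == region.label
        means = {
            ch: float(image.plane(ch)[mask].mean()) for ch in CHANNELS
        }
        nucleus_id += 1
        nuclei.append(
            NucleusObject(
                nucleus_id=nucleus_id,
                mask=mask,
                centroid=(float(cx), float(cy)),
                area_um2=float(area_um2),
                mean_intensity=means,
                is_podocyte=False,
            )
        )
    return nuclei


def classify_podocyte_nuclei(
    nuclei: list[NucleusObject], thresholds: ThresholdSet
) -> list[NucleusObject]:
    """Flag podocyte nuclei by p57 positivity.

    A nucleus is a podocyte iff its mean p57 intensity over the nuclear mask is
    strictly above the calibrated threshold.  Order and all other fields are
    preserved; the operation is idempotent.
    """
    thr = thresholds["p57"]
    return [
        dataclasses.replace(n, is_podocyte=bool(n.mean_intensity["p57"] > thr))
        for n in nuclei
    ]


def segment_nqo1_area(
    image: MultiplexImage,
    roi: GlomerulusROI,
    thresholds: ThresholdSet,
    params: SegmentationParams | None = None,
) -> CompartmentMask:
    """Segment the NQO1-positive area (podocyte cytoplasmic compartment).

    ROI-interior pixels whose raw NQO1 intensity is strictly above the
    calibrated threshold, after removing connected components smaller than
    ``params.min_nqo1_component_um2`` (default 2 µm²).
    """
    params = params or SegmentationParams()
    roi_mask = roi.mask(image.shape)
    mask = roi_mask & (image.plane("nqo1") > thresholds["nqo1"])
    if mask.any() and params.min_nqo1_component_um2 > 0:
        px_area = image.pixel_size_um**2
        min_px = int(np.ceil(params.min_nqo1_component_um2 / px_area))
        labels = label(mask)
        counts = np.bincount(labels.ravel())
        keep = counts >= min_px
        keep[0] = False
        mask = keep[labels]
    area = float(mask.sum() * image.pixel_size_um**2)
    return CompartmentMask(mask=mask, area_um2=area, channel="nqo1")


def export_label_mask(nuclei: list[NucleusObject], shape: tuple[int, int], path) -> None:
    """Write nuclei as a single-plane label TIFF (pixel value = nucleus_id)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for n in nuclei:
        labels[n.mask] = n.nucleus_id
    tifffile.imwrite(Path(path), labels)


def export_mask_geojson(compartment: CompartmentMask, path) -> None:
    """Write a compartment mask as GeoJSON polygons for overlay in viewers.

    Contours are traced at the 0.5 level of the binary mask; this is an
    approximate outline intended for visual review, not re-analysis.
    """
    features = []
    padded = np.pad(compartment.mask.astype(float), 1)
    for i, contour in enumerate(find_contours(padded, 0.5)):
        ring = [[float(c - 1), float(r - 1)] for r, c in contour]
        if len(ring) < 4:
            continue
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"classification": {"name": "NQO1PosArea"}, "index": i},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))
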