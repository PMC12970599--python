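"""Instance segmentation post-processing.

The deep segmentation model itself is out of scope: this module turns masks
(from any source — a detector, polygon labels, or the classical threshold
fallback below) into clean per-instance shapes.  Touching seeds are split by
marker-controlled watershed seeded at peaks of the Euclidean distance
transform, the standard approach for separating convex-ish touching objects.
A lightweight QC step aggregates reconstruction errors into the per-dataset
report used to benchmark reconstruction approaches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from ._geometry import fill_contour, outer_contour
from .io_formats import PolygonLabel, polygon_to_mask

__all__ = [
    "InstanceShape",
    "ReconstructionReport",
    "threshold_segment",
    "separate_touching",
    "extract_instances",
    "qc_and_report",
    "per_season_average",
]


def per_season_average(total_count: int, n_seasons: int) -> int:
    """Average element count per season, rounded half up to a whole count."""
    if n_seasons <= 0:
        raise ValueError("n_seasons must be positive")
    return int(np.floor(total_count / n_seasons + 0.5))


@dataclass
class InstanceShape:
    """One segmented fruit: outer contour + local mask + provenance.

    ``mask`` is cropped to the bounding box; ``offset`` is its (row, col)
    origin in the full image.  ``contour`` is in full-image (row, col)
    coordinates and rasterizes back to exactly the foreground (holes are
    filled on extraction).
    """

    instance_id: int
    contour: np.ndarray
    mask: np.ndarray
    offset: tuple[int, int]
    source: str = "watershed"
    qc_flags: set = field(default_factory=set)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (rows.mean() + self.offset[0], cols.mean() + self.offset[1])

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.mask
        return out


@dataclass
class ReconstructionReport:
    """Error accounting for one dataset/reconstruction combination."""

    dataset: str
    errors: int
    total_elements: int
    phenotyped: int

    def __post_init__(self) -> None:
        if self.phenotyped > self.total_elements:
            raise ValueError("phenotyped cannot exceed total_elements")

    @property
    def error_pct(self) -> float:
        """Percentage of erroneous elements, rounded to 2 decimals."""
        if self.total_elements == 0:
            return 0.0
        return round(100.0 * self.errors / self.total_elements, 2)


def threshold_segment(gray_patch: np.ndarray, min_area: int = 64) -> np.ndarray:
    """Classical foreground segmentation: bright objects on dark background.

    Otsu threshold, hole filling, and removal of specks below ``min_area``.
    This is the pluggable fallback segmenter for scenes shot on a dark
    surface; a learned model can replace it anywhere a mask is accepted.
    """
    patch = np.asarray(gray_patch, dtype=float)
    if patch.ndim != 2:
        raise ValueError("threshold_segment expects a single-channel patch")
    if patch.max() == patch.min():
        warnings.warn("constant-intensity patch; returning empty mask")
        return np.zeros(patch.shape, dtype=bool)
    mask = patch > threshold_otsu(patch)
    mask = ndi.binary_fill_holes(mask)
    return remove_small_objects(mask, max_size=min_area - 1)


def separate_touching(mask: np.ndarray, min_peak_distance: int = 20) -> np.ndarray:
    """Split touching objects by distance-transform watershed.

    Peaks of the Euclidean distance transform separated by at least
    ``min_peak_distance`` pixels seed a marker-controlled watershed on the
    inverted distance map.  A sensible default for the minimum distance is
    half the expected minor-axis length in pixels.  Returns an int label
    raster (0 = background) partitioning the foreground exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=int(min_peak_distance), labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    if len(peaks) == 0:
        labels, _ = ndi.label(mask)
        return labels.astype(np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-distance, markers, mask=mask).astype(np.int32)


def _instance_from_mask(
    full_mask: np.ndarray, instance_id: int, source: str
) -> InstanceShape:
    filled = ndi.binary_fill_holes(full_mask)
    rows, cols = np.nonzero(filled)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    contour = outer_contour(filled)
    return InstanceShape(
        instance_id=instance_id,
        contour=contour,
        mask=filled[r0:r1, c0:c1].copy(),
        offset=(int(r0), int(c0)),
        source=source,
    )


def extract_instances(
    labeled: np.ndarray | list[PolygonLabel],
    image_size: tuple[int, int] | None = None,
    min_area: int = 1,
) -> list[InstanceShape]:
    """Build InstanceShape objects from a label raster or polygon labels.

    Outer contours only; interior holes are filled before measurement (seed
    wrinkles would otherwise corrupt solidity).  Instances are sorted
    top-to-bottom then left-to-right by centroid and renumbered accordingly.
    """
    instances: list[InstanceShape] = []
    if isinstance(labeled, np.ndarray):
        for lab in np.unique(labeled):
            if lab == 0:
                continue
            m = labeled == lab
            if m.sum() < min_area:
                continue
            instances.append(_instance_from_mask(m, int(lab), "watershed"))
    else:
        if image_size is None:
            raise ValueError("image_size is required for polygon labels")
        for i, label in enumerate(labeled):
            m = polygon_to_mask(label, image_size)
            if m.sum() < min_area:
                continue
            instances.append(_instance_from_mask(m, i, "polygon_label"))
    # row-banded reading order: quantize rows by median instance height
    if instances:
        heights = [inst.mask.shape[0] for inst in instances]
        band = max(1.0, float(np.median(heights)))
        instances.sort(
            key=lambda s: (int(s.centroid[0] // band), s.centroid[1], s.centroid[0])
        )
        for new_id, inst in enumerate(instances):
            inst.instance_id = new_id
    return instances


def qc_and_report(
    instances: list[InstanceShape],
    expected_count: int | None = None,
    min_area: int = 0,
    border_margin: int = 0,
    image_size: tuple[int, int] | None = None,
    dataset: str = "",
) -> tuple[list[InstanceShape], ReconstructionReport]:
    """Flag suspect instances and aggregate a reconstruction report.

    Under-size instances are dropped and counted as errors; border-touching
    instances are flagged but kept.  If ``expected_count`` is given, the
    absolute count mismatch after filtering is added to the error tally
    (``total_elements`` then reflects the expected count).  ``error_pct`` in
    the returned report is ``round(100 * errors / total_elements, 2)``.
    """
    kept: list[InstanceShape] = []
    errors = 0
    for inst in instances:
        if inst.area_px < min_area:
            inst.qc_flags.add("undersize")
            errors += 1
            continue
        if border_margin and image_size is not None:
            h, w = image_size[1], image_size[0]
            r0, c0 = inst.offset
            r1, c1 = r0 + inst.mask.shape[0], c0 + inst.mask.shape[1]
            if r0 < border_margin or c0 < border_margin or r1 > h - border_margin or c1 > w - border_margin:
                inst.qc_flags.add("border")
        kept.append(inst)
    if expected_count is not None:
        mismatch = abs(len(kept) - expected_count)
        if mismatch:
            errors += mismatch
        total = expected_count
    else:
        total = len(instances)
    report = ReconstructionReport(
        dataset=dataset,
        errors=errors,
        total_elements=total,
        phenotyped=min(len(kept), total),
    )
    return kept, report
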