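"""Patch slicing, dataset splitting, and full-image reconstruction.

Large scene images are cut into fixed-size patches (default 320 px) for
per-patch segmentation; patch masks are stitched back by logical OR, and
per-patch polygon detections can be merged across overlapping tiles by a
greedy mask-IoU union (a minimal sliced-inference merge).

Edge policy: patches at the right/bottom edge are clipped to the image
bounds rather than padded, which makes slice -> reconstruct exactly the
identity for any mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import fill_contour, outer_contour
from .io_formats import SplitManifest

__all__ = [
    "PatchGrid",
    "slice_image",
    "split_patches",
    "reconstruct_mask",
    "merge_sliced_detections",
]


@dataclass
class PatchGrid:
    """Tiling of an image: offsets are (x0, y0), row-major."""

    patch_size: int
    overlap: int
    offsets: list[tuple[int, int]]
    image_size: tuple[int, int]  # (width, height)

    def boxes(self) -> list[tuple[int, int, int, int]]:
        """Per-patch (x0, y0, x1, y1), clipped to image bounds."""
        w, h = self.image_size
        return [
            (x0, y0, min(x0 + self.patch_size, w), min(y0 + self.patch_size, h))
            for x0, y0 in self.offsets
        ]


def _starts(extent: int, patch: int, step: int) -> list[int]:
    starts = [0]
    while starts[-1] + patch < extent:
        starts.append(starts[-1] + step)
    return starts


def slice_image(
    image: np.ndarray, patch_size: int = 320, overlap: int = 0
) -> tuple[list[np.ndarray], PatchGrid]:
    """Cut an image or mask into patches covering every pixel.

    Patches are returned row-major.  If ``patch_size`` exceeds both image
    dimensions a single whole-image patch is returned with a warning.
    """
    if patch_size < 32:
        raise ValueError("patch_size must be >= 32")
    if not 0 <= overlap < patch_size:
        raise ValueError("overlap must be in [0, patch_size)")
    h, w = image.shape[:2]
    if patch_size > h and patch_size > w:
        warnings.warn("patch_size exceeds both image dimensions; using one patch")
        grid = PatchGrid(patch_size, overlap, [(0, 0)], (w, h))
        return [image.copy()], grid
    step = patch_size - overlap
    offsets = [(x0, y0) for y0 in _starts(h, patch_size, step) for x0 in _starts(w, patch_size, step)]
    grid = PatchGrid(patch_size, overlap, offsets, (w, h))
    patches = [image[y0:y1, x0:x1] for x0, y0, x1, y1 in grid.boxes()]
    return patches, grid


def split_patches(
    patch_ids: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitManifest:
    """Random proportional train/val/test split, deterministic per seed.

    Subset sizes follow the largest-remainder rule, so each realized size is
    within one item of ``fraction * n``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(patch_ids)
    raw = np.array(fractions) * n
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    entries: list[tuple[str, str]] = []
    pos = 0
    for subset, size in zip(SplitManifest.SUBSETS, sizes):
        for idx in order[pos : pos + size]:
            entries.append((patch_ids[idx], subset))
        pos += size
    entries.sort(key=lambda e: e[0])
    return SplitManifest(entries=entries, fractions=tuple(fractions), seed=seed)


def reconstruct_mask(patch_masks: list[np.ndarray], grid: PatchGrid) -> np.ndarray:
    """Stitch patch masks back to full size (logical OR in overlaps)."""
    if len(patch_masks) != len(grid.offsets):
        raise ValueError(
            f"expected {len(grid.offsets)} patch masks, got {len(patch_masks)}"
        )
    w, h = grid.image_size
    out = np.zeros((h, w), dtype=bool)
    for mask, (x0, y0, x1, y1) in zip(patch_masks, grid.boxes()):
        if mask.shape != (y1 - y0, x1 - x0):
            raise ValueError("patch mask shape does not match its grid box")
        out[y0:y1, x0:x1] |= mask.astype(bool)
    return out


def _mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    if inter == 0:
        return 0.0
    return inter / np.logical_or(a, b).sum()


def merge_sliced_detections(
    detections: list[tuple[np.ndarray, float, tuple[int, int]]],
    image_size: tuple[int, int],
    iou_threshold: float = 0.5,
) -> list[tuple[np.ndarray, float]]:
    """Merge per-patch polygon detections into global instances.

    Parameters
    ----------
    detections:
        ``(polygon, confidence, (x0, y0))`` triples; polygons are ``(N, 2)``
        ``(x, y)`` arrays in patch-local pixel coordinates.
    image_size:
        Full ``(width, height)``; polygons are shifted to this frame.
    iou_threshold:
        Pairs of detections whose rasterized masks overlap with IoU at or
        above this are greedily unioned; the union keeps the highest
        confidence of its members.

    Returns
    -------
    list of ``(polygon, confidence)`` with polygons as global (x, y) arrays,
    ordered by descending confidence.  Merging is idempotent.
    """
    w, h = image_size
    entries = []
    for polygon, conf, (x0, y0) in detections:
        poly = np.asarray(polygon, dtype=float) + np.array([x0, y0], dtype=float)
        mask = fill_contour(poly[:, ::-1], (h, w))
        entries.append({"mask": mask, "conf": float(conf)})
    entries.sort(key=lambda e: -e["conf"])

    merged: list[dict] = []
    for entry in entries:
        for kept in merged:
            if _mask_iou(entry["mask"], kept["mask"]) >= iou_threshold:
                kept["mask"] |= entry["mask"]
                kept["conf"] = max(kept["conf"], entry["conf"])
                break
        else:
            merged.append(entry)

    out = []
    for kept in merged:
        contour = outer_contour(kept["mask"])  # (row, col)
        out.append((contour[:, ::-1].copy(), kept["conf"]))
    return out
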