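"""Readers and writers for on-disk artifacts.

Supported formats:

* YOLO Segmentation 1.0 polygon label files — one polygon per line,
  ``class_id x1 y1 x2 y2 ...`` with coordinates normalized to ``[0, 1]``
  relative to full image width/height (no letterboxing);
* 8-bit single-channel PNG instance masks (0 background, 255 foreground);
* CSV trait tables keyed by (genotype, year, instance_id);
* JSON train/val/test split manifests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from ._geometry import fill_contour, shoelace_area

__all__ = [
    "PolygonLabel",
    "SplitManifest",
    "YoloSegFormatError",
    "read_yolo_seg",
    "write_yolo_seg",
    "polygon_to_mask",
    "read_mask_png",
    "write_mask_png",
    "read_trait_table",
    "write_trait_table",
    "TRAIT_UNITS",
]

#: Units of the standard trait columns written by :mod:`fruitmorph.morphology`.
TRAIT_UNITS = {
    "length": "mm",
    "width": "mm",
    "area": "mm2",
    "perimeter": "mm",
    "hull_area": "mm2",
    "solidity": "1",
    "aspect_ratio": "1",
    "circularity": "1",
    "ellipse_ratio": "1",
    "width_at_25": "mm",
    "width_at_50": "mm",
    "width_at_75": "mm",
    "sym_vertical": "1",
    "sym_horizontal": "1",
    "sym_shoulder": "1",
    "color_L": "L*",
    "color_a": "a*",
    "color_b": "b*",
    "weight": "g",
    "weight_ratio_kernel_shell": "1",
    "thickness_est": "mm",
    "globosity": "1",
}


class YoloSegFormatError(ValueError):
    """Malformed YOLO Segmentation 1.0 label line."""


@dataclass
class PolygonLabel:
    """One instance polygon in normalized image coordinates.

    ``vertices`` is an ``(N, 2)`` float array of ``(x, y)`` pairs in
    ``[0, 1]``; ``x`` runs along image width (columns), ``y`` along height
    (rows).  The polygon is implicitly closed.
    """

    class_id: int
    vertices: np.ndarray
    source_image: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (N, 2) array")
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if self.vertices.min() < 0.0 or self.vertices.max() > 1.0:
            raise ValueError("normalized vertices must lie in [0, 1]")

    def pixel_vertices(self, image_size: tuple[int, int]) -> np.ndarray:
        """Vertices in pixel coordinates for an image of (width, height)."""
        w, h = image_size
        return self.vertices * np.array([w, h], dtype=float)


@dataclass
class SplitManifest:
    """Assignment of patch identifiers to train/val/test subsets."""

    entries: list[tuple[str, str]]
    fractions: tuple[float, float, float]
    seed: int

    SUBSETS = ("train", "val", "test")

    def __post_init__(self) -> None:
        for _, subset in self.entries:
            if subset not in self.SUBSETS:
                raise ValueError(f"unknown subset {subset!r}")

    def ids(self, subset: str) -> list[str]:
        return [pid for pid, s in self.entries if s == subset]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fractions": list(self.fractions),
            "seed": self.seed,
            "entries": [[pid, s] for pid, s in self.entries],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SplitManifest":
        payload = json.loads(Path(path).read_text())
        return cls(
            entries=[(pid, s) for pid, s in payload["entries"]],
            fractions=tuple(payload["fractions"]),
            seed=int(payload["seed"]),
        )


def read_yolo_seg(
    label_path: str | Path,
    image_size: tuple[int, int] | None = None,
    source_image: str | None = None,
) -> list[PolygonLabel]:
    """Parse a YOLO Segmentation 1.0 label file.

    Parameters
    ----------
    label_path:
        Text file with one polygon per line: ``class_id x1 y1 x2 y2 ...``.
    image_size:
        Optional ``(width, height)`` in pixels.  Only used to validate that
        pixel coordinates can be derived; labels always retain normalized
        coordinates and expose :meth:`PolygonLabel.pixel_vertices`.
    """
    path = Path(label_path)
    labels: list[PolygonLabel] = []
    name = source_image if source_image is not None else path.stem
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        try:
            class_id = int(parts[0])
            coords = np.array([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise YoloSegFormatError(f"{path}:{lineno}: unparsable token") from exc
        if coords.size % 2 != 0:
            raise YoloSegFormatError(f"{path}:{lineno}: odd coordinate count")
        if coords.size < 6:
            raise YoloSegFormatError(f"{path}:{lineno}: fewer than 3 vertices")
        if coords.min() < 0.0 or coords.max() > 1.0:
            raise YoloSegFormatError(f"{path}:{lineno}: coordinate outside [0, 1]")
        if class_id < 0:
            raise YoloSegFormatError(f"{path}:{lineno}: negative class id")
        labels.append(
            PolygonLabel(class_id, coords.reshape(-1, 2), source_image=name)
        )
    if image_size is not None:
        for label in labels:
            label.pixel_vertices(image_size)
    return labels


def write_yolo_seg(labels: list[PolygonLabel], path: str | Path) -> None:
    """Write labels as YOLO Segmentation 1.0, one polygon per line."""
    lines = []
    for label in labels:
        coords = " ".join(f"{v:.6f}" for v in label.vertices.ravel())
        lines.append(f"{label.class_id} {coords}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def polygon_to_mask(
    label: PolygonLabel, image_size: tuple[int, int]
) -> np.ndarray:
    """Rasterize one polygon label into a boolean (height, width) mask.

    Uses even-odd interior filling of the pixel-center lattice; for polygons
    above ~1000 px² the pixel count agrees with the shoelace area to within
    2%.  A degenerate (zero-area) polygon yields an empty mask and a warning.
    """
    w, h = image_size
    pixel = label.pixel_vertices(image_size)
    if shoelace_area(pixel) == 0.0:
        warnings.warn("degenerate zero-area polygon rasterized to empty mask")
        return np.zeros((h, w), dtype=bool)
    # fill_contour expects (row, col) = (y, x)
    return fill_contour(pixel[:, ::-1], (h, w))


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read an 8-bit PNG mask; any non-zero pixel is foreground."""
    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a trait CSV and check key uniqueness.

    Key columns are whichever of ``genotype``, ``year``, ``instance_id`` are
    present; duplicate keys raise ``ValueError``.
    """
    df = pd.read_csv(path)
    keys = [c for c in ("genotype", "year", "instance_id") if c in df.columns]
    if keys and df.duplicated(subset=keys).any():
        raise ValueError(f"duplicate ({', '.join(keys)}) keys in {path}")
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
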