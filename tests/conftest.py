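"""Shared fixtures: small rasters and generated shapes with ground truth."""

import numpy as np
import pytest
from skimage.draw import disk

from fruitmorph.synthetic import SeedShapeParams, child_rng, generate_shape, random_shape_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disc(radius: int, pad: int = 10, offset=(0.0, 0.0)) -> np.ndarray:
    size = 2 * radius + 2 * pad + 1
    mask = np.zeros((size, size), dtype=bool)
    mask[disk((radius + pad + offset[0], radius + pad + offset[1]), radius, shape=mask.shape)] = True
    return mask


@pytest.fixture
def ellipse_shape():
    """A p=1 generated shape: exactly an ellipse (24 x 13 mm at 6 px/mm)."""
    return generate_shape(SeedShapeParams(length=24, width=13, tip_sharpness=1.0), px_per_mm=6.0)


@pytest.fixture
def random_shapes():
    """Thirty realistic shapes with analytic ground truth (6 px/mm)."""
    gen = child_rng(777, "fixtures")
    return [generate_shape(random_shape_params(gen, seed=i), px_per_mm=6.0) for i in range(30)]


def random_blob_mask(rng: np.random.Generator, size: int = 90) -> np.ndarray:
    """A connected random blob (union of discs, holes filled)."""
    from scipy import ndimage as ndi

    mask = np.zeros((size, size), dtype=bool)
    center = size // 2
    mask[disk((center, center), size // 6, shape=mask.shape)] = True
    for _ in range(4):
        dr, dc = rng.integers(-size // 6, size // 6, size=2)
        mask[disk((center + dr, center + dc), int(rng.integers(size // 10, size // 5)), shape=mask.shape)] = True
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    sizes = ndi.sum(mask, labels, range(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))
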