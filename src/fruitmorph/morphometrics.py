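"""Shape-space analysis: elliptic Fourier descriptors and mask PCA.

Elliptic Fourier analysis (EFA) expands a closed contour, parameterized by
cumulative chord length ``t`` over total length ``T``, as

    x(t) = A0 + sum_n a_n cos(2*pi*n*t/T) + b_n sin(2*pi*n*t/T)
    y(t) = C0 + sum_n c_n cos(2*pi*n*t/T) + d_n sin(2*pi*n*t/T)

with the classical closed-form coefficients for a piecewise-linear contour
(the chain-summation formulation of Kuhl & Giardina).  PCA on the harmonic
coefficients (EF-PCs) and on flattened registered binary masks (PB-PCs)
yields quantitative shape traits; components explaining at least 1% of the
variance are retained by default.  k-means sweeps over the scores with
within-group sum-of-squares elbow diagnostics, and shapes can be
back-projected from any point of the score space (mean ± m·SD sweeps).

Shapes entering this module are assumed to be pre-aligned tip-down and
pre-flipped (see :mod:`fruitmorph.morphology`); EFA first-harmonic
normalization is therefore OFF by default and available as a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from ._geometry import resample_closed

__all__ = [
    "EFACoefficients",
    "ShapePCAModel",
    "ClusterResult",
    "efa_forward",
    "efa_inverse",
    "harmonic_power",
    "pca_fit",
    "register_mask",
    "pc_shape_sweep",
    "kmeans_sweep",
]


@dataclass
class EFACoefficients:
    """Per-harmonic (a, b, c, d) coefficients plus DC terms."""

    coeffs: np.ndarray  # (H, 4) columns a_n, b_n, c_n, d_n
    a0: float
    c0: float
    normalized: bool = False

    @property
    def harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flatten(self, include_dc: bool = False) -> np.ndarray:
        flat = self.coeffs.ravel()
        if include_dc:
            flat = np.concatenate([[self.a0, self.c0], flat])
        return flat


def _closed_xy(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("contour must be an (N, 2) array")
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    if len(c) < 3:
        raise ValueError("need at least 3 distinct contour points")
    return c[:, 0], c[:, 1]


def efa_forward(
    contour: np.ndarray,
    harmonics: int = 10,
    normalize: bool = False,
    parameterization: str = "chord",
) -> EFACoefficients:
    """Elliptic Fourier coefficients of a closed (x, y) polyline.

    ``contour`` is ``(N, 2)`` with columns (x, y); at least ``4 *
    harmonics`` points are recommended for stable high harmonics (a warning
    is issued below that).  ``normalize`` applies the standard
    first-harmonic normalization (rotation/starting-point/size invariant:
    a1 > 0, b1 = c1 = 0).

    ``parameterization`` selects how the curve parameter advances between
    vertices: ``"chord"`` (default) uses cumulative chord length — the
    classical choice, independent of how densely each arc is sampled —
    while ``"index"`` advances uniformly per vertex, so a contour sampled
    uniformly in an analytic parameter (e.g. the ellipse angle) decomposes
    exactly along that parameter: an ellipse then is a pure first harmonic,
    which under chord length it is not.
    """
    if harmonics < 1:
        raise ValueError("need at least 1 harmonic")
    if parameterization not in ("chord", "index"):
        raise ValueError("parameterization must be 'chord' or 'index'")
    x, y = _closed_xy(contour)
    if len(x) < 4 * harmonics:
        warnings.warn(
            f"{len(x)} contour points for {harmonics} harmonics; "
            "recommend at least 4 per harmonic"
        )
    dx = np.diff(np.append(x, x[0]))
    dy = np.diff(np.append(y, y[0]))
    dt = np.hypot(dx, dy)
    keep = dt > 0
    dx, dy, dt = dx[keep], dy[keep], dt[keep]
    if parameterization == "index":
        dt = np.ones_like(dt)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]

    n = np.arange(1, harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :] / T
    dcos = np.cos(phi[:, 1:]) - np.cos(phi[:, :-1])
    dsin = np.sin(phi[:, 1:]) - np.sin(phi[:, :-1])
    const = T / (2.0 * np.pi**2 * n.ravel() ** 2)

    vx = dx / dt
    vy = dy / dt
    a = const * (dcos @ vx)
    b = const * (dsin @ vx)
    c = const * (dcos @ vy)
    d = const * (dsin @ vy)

    # DC terms: mean of the piecewise-linear x(t), y(t) over one period
    xs = np.append(x[keep.nonzero()[0]], x[0]) if not keep.all() else np.append(x, x[0])
    ys = np.append(y[keep.nonzero()[0]], y[0]) if not keep.all() else np.append(y, y[0])
    a0 = float(np.sum(0.5 * (xs[1:] + xs[:-1]) * dt) / T)
    c0 = float(np.sum(0.5 * (ys[1:] + ys[:-1]) * dt) / T)

    out = EFACoefficients(np.column_stack([a, b, c, d]), a0, c0, normalized=False)
    if normalize:
        out = _normalize_first_harmonic(out)
    return out


def _normalize_first_harmonic(coeffs: EFACoefficients) -> EFACoefficients:
    a1, b1, c1, d1 = coeffs.coeffs[0]
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2)
    H = coeffs.harmonics
    rotated = np.empty_like(coeffs.coeffs)
    for i in range(H):
        n = i + 1
        m = coeffs.coeffs[i].reshape(2, 2)
        rot_t = np.array(
            [[np.cos(n * theta), -np.sin(n * theta)], [np.sin(n * theta), np.cos(n * theta)]]
        )
        rotated[i] = (m @ rot_t).ravel()
    a1s, _, c1s, _ = rotated[0]
    psi = np.arctan2(c1s, a1s)
    rot_s = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for i in range(H):
        rotated[i] = (rot_s @ rotated[i].reshape(2, 2)).ravel()
    scale = rotated[0, 0]
    rotated /= scale
    return EFACoefficients(rotated, coeffs.a0, coeffs.c0, normalized=True)


def efa_inverse(coeffs: EFACoefficients, n_points: int = 200) -> np.ndarray:
    """Reconstruct an (x, y) contour by summing the harmonic series."""
    t = np.linspace(0.0, 1.0, n_points, endpoint=False)
    n = np.arange(1, coeffs.harmonics + 1)[:, None]
    phi = 2.0 * np.pi * n * t[None, :]
    cos, sin = np.cos(phi), np.sin(phi)
    a, b, c, d = coeffs.coeffs.T
    x = coeffs.a0 + a @ cos + b @ sin
    y = coeffs.c0 + c @ cos + d @ sin
    return np.column_stack([x, y])


def harmonic_power(coeffs_set: EFACoefficients | list[EFACoefficients]) -> dict:
    """Per-harmonic power and cumulative fraction, averaged over shapes.

    Power of harmonic n is ``(a_n² + b_n² + c_n² + d_n²) / 2``.
    """
    if isinstance(coeffs_set, EFACoefficients):
        coeffs_set = [coeffs_set]
    if not coeffs_set:
        raise ValueError("need at least one shape")
    powers = np.mean(
        [np.sum(c.coeffs**2, axis=1) / 2.0 for c in coeffs_set], axis=0
    )
    cumulative = np.cumsum(powers) / powers.sum()
    return {"power": powers, "cumulative_fraction": cumulative}


@dataclass
class ShapePCAModel:
    """Centered PCA of a shape feature matrix (EFA coefficients or pixels)."""

    basis: str  # "efa" or "pixel"
    mean: np.ndarray
    components: np.ndarray  # (k, n_features) rows are loadings
    explained_variance: np.ndarray  # per-component variance
    explained_variance_fractions: np.ndarray  # descending, sums to <= 1
    scores: np.ndarray  # (n_shapes, k)
    retained: int  # components with fraction >= retain_threshold
    retain_threshold: float = 0.01
    feature_shape: tuple | None = None  # raster shape for the pixel basis
    harmonics: int | None = None  # for the efa basis

    def back_project(self, score_vector: np.ndarray) -> np.ndarray:
        """Feature vector at a point of score space."""
        sv = np.asarray(score_vector, dtype=float)
        return self.mean + sv @ self.components[: len(sv)]


def pca_fit(
    matrix: np.ndarray,
    basis: str = "efa",
    retain_threshold: float = 0.01,
    feature_shape: tuple | None = None,
    harmonics: int | None = None,
) -> ShapePCAModel:
    """PCA via SVD of the centered matrix.

    Component signs are fixed by making each component's largest-magnitude
    loading positive; fractions are descending and components with a
    variance fraction of at least ``retain_threshold`` (default the 1% rule)
    are counted as retained.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 3 shapes and >= 2 features")
    mean = X.mean(axis=0)
    centered = X - mean
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    var = s**2 / (X.shape[0] - 1)
    fractions = s**2 / np.sum(s**2)
    retained = max(1, int(np.sum(fractions >= retain_threshold)))
    return ShapePCAModel(
        basis=basis,
        mean=mean,
        components=vt,
        explained_variance=var,
        explained_variance_fractions=fractions,
        scores=u * s,
        retained=retained,
        retain_threshold=retain_threshold,
        feature_shape=feature_shape,
        harmonics=harmonics,
    )


def register_mask(mask: np.ndarray, out_size: tuple[int, int] = (128, 128)) -> np.ndarray:
    """Flatten an aligned mask into a fixed-size registration raster.

    The mask is cropped to its bounding box, isotropically scaled to fit
    ``out_size`` (aspect ratio preserved), centered with padding, binarized
    at 0.5, and flattened row-major to a float vector.
    """
    m = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(m)
    if len(rows) == 0:
        raise ValueError("empty mask")
    h = rows.max() - rows.min() + 1
    w = cols.max() - cols.min() + 1
    oh, ow = out_size
    margin = 2  # keep the boundary off the raster edge
    factor = min((oh - 2 * margin) / h, (ow - 2 * margin) / w)
    # single continuous affine warp: bbox center -> raster center, uniform
    # scale; sub-pixel placement keeps the registration smooth in the shape
    # parameters (no integer rounding jumps between similar shapes)
    cr = (rows.min() + rows.max()) / 2.0
    cc = (cols.min() + cols.max()) / 2.0
    center = np.array([(oh - 1) / 2.0, (ow - 1) / 2.0])

    rr, ccc = np.meshgrid(np.arange(oh, dtype=float), np.arange(ow, dtype=float), indexing="ij")
    src_r = (rr - center[0]) / factor + cr
    src_c = (ccc - center[1]) / factor + cc
    from scipy.ndimage import map_coordinates

    sampled = map_coordinates(
        m.astype(float), np.stack([src_r, src_c]), order=1, mode="constant", cval=0.0
    )
    return (sampled >= 0.5).astype(float).ravel()


def pc_shape_sweep(
    model: ShapePCAModel,
    component: int,
    multiples: np.ndarray | list = (-3, -2, -1, 0, 1, 2, 3),
    n_points: int = 200,
) -> list[np.ndarray]:
    """Back-project mean + m·SD along one component for each multiple.

    Returns contours (``(n_points, 2)``) for the EFA basis or thresholded
    mask rasters for the pixel basis.  Multiple 0 is exactly the mean shape.
    """
    if not 0 <= component < model.components.shape[0]:
        raise IndexError("component index out of range")
    sd = float(np.sqrt(model.explained_variance[component]))
    shapes = []
    for m in multiples:
        vec = model.mean + float(m) * sd * model.components[component]
        if model.basis == "pixel":
            if model.feature_shape is None:
                raise ValueError("pixel-basis model lacks feature_shape")
            shapes.append(vec.reshape(model.feature_shape) >= 0.5)
        else:
            H = model.harmonics or vec.size // 4
            coeffs = EFACoefficients(vec.reshape(H, 4), 0.0, 0.0)
            shapes.append(efa_inverse(coeffs, n_points))
    return shapes


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray  # in score space
    wss: float
    centroid_shapes: list[np.ndarray] | None = None


def kmeans_sweep(
    scores: np.ndarray,
    k_range=range(1, 11),
    seed: int = 0,
    restarts: int = 10,
    model: ShapePCAModel | None = None,
    n_points: int = 200,
) -> tuple[list[ClusterResult], np.ndarray]:
    """k-means over a score matrix for each k, with elbow diagnostics.

    Uses best-of-``restarts`` initializations under a shared seed so the
    within-group sum-of-squares curve is reproducible and non-increasing.
    If a fitted PCA model is supplied, each centroid is back-projected to a
    shape (contour or mask raster depending on the basis).
    """
    X = np.asarray(scores, dtype=float)
    results = []
    wss_curve = []
    for k in k_range:
        if k > X.shape[0]:
            raise ValueError(f"k={k} exceeds the number of shapes {X.shape[0]}")
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(X)
        shapes = None
        if model is not None:
            shapes = []
            for centroid in km.cluster_centers_:
                vec = model.back_project(centroid[: model.components.shape[0]])
                if model.basis == "pixel":
                    shapes.append(vec.reshape(model.feature_shape) >= 0.5)
                else:
                    H = model.harmonics or vec.size // 4
                    shapes.append(efa_inverse(EFACoefficients(vec.reshape(H, 4), 0.0, 0.0), n_points))
        results.append(
            ClusterResult(
                k=k,
                assignments=km.labels_.copy(),
                centroids=km.cluster_centers_.copy(),
                wss=float(km.inertia_),
                centroid_shapes=shapes,
            )
        )
        wss_curve.append(float(km.inertia_))
    return results, np.asarray(wss_curve)
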