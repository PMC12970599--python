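"""Image standardization before measurement.

Three independent calibrations:

* **Color** — a single affine map in RGB fitted by least squares from
  observed color-chart patch means to their reference values, then applied
  per pixel to every image of a session.
* **Geometry** — pinhole camera intrinsics plus radial (k1, k2, k3) and
  tangential (p1, p2) lens distortion, estimated from chessboard corner
  grids of known square size (planar-target calibration: homography-based
  closed-form initialization refined by joint nonlinear least squares).
  Undistortion is applied before color correction (geometric before
  photometric).
* **Scale** — physical pixel size from a near-circular reference object of
  known diameter (e.g., a coin), using the equivalent-circle diameter from
  area, which is robust to boundary noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from ._geometry import perimeter_of_mask

__all__ = [
    "ColorTransform",
    "CameraModel",
    "PixelScale",
    "CalibrationError",
    "fit_color_transform",
    "apply_color_transform",
    "calibrate_camera",
    "undistort",
    "undistort_points",
    "pixel_scale_from_reference",
]


class CalibrationError(RuntimeError):
    pass


@dataclass
class ColorTransform:
    """Affine channel map: corrected = matrix @ rgb + offset."""

    matrix: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    fit_residual: float  # RMS over chart patches

    kind = "affine"


def fit_color_transform(
    observed_patches: np.ndarray, reference_patches: np.ndarray
) -> ColorTransform:
    """Least-squares affine map from observed to reference patch colors.

    Needs at least 4 linearly independent patch pairs.  The fit is exactly
    invariant to patch ordering.
    """
    obs = np.asarray(observed_patches, dtype=float)
    ref = np.asarray(reference_patches, dtype=float)
    if obs.shape != ref.shape or obs.ndim != 2 or obs.shape[1] != 3:
        raise ValueError("patch arrays must both be (n, 3)")
    n = obs.shape[0]
    if n < 4:
        raise ValueError("need at least 4 patch pairs")
    design = np.hstack([obs, np.ones((n, 1))])
    if np.linalg.matrix_rank(design) < 4:
        raise np.linalg.LinAlgError("rank-deficient patch set")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    matrix = coef[:3].T
    offset = coef[3]
    resid = design @ coef - ref
    rms = float(np.sqrt(np.mean(resid**2)))
    return ColorTransform(matrix=matrix, offset=offset, fit_residual=rms)


def apply_color_transform(image: np.ndarray, transform: ColorTransform) -> np.ndarray:
    """Apply a fitted color transform per pixel, clipped to channel range."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel image")
    flat = img.reshape(-1, 3).astype(float)
    out = flat @ transform.matrix.T + transform.offset
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max).astype(img.dtype)
    else:
        out = np.clip(out, 0.0, 1.0).astype(img.dtype)
    return out.reshape(img.shape)


@dataclass
class CameraModel:
    """Pinhole intrinsics + radial/tangential distortion."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    reprojection_rms: float = 0.0

    def distort_normalized(self, xy: np.ndarray) -> np.ndarray:
        """Apply the distortion model to normalized camera coordinates."""
        x, y = xy[:, 0], xy[:, 1]
        r2 = x * x + y * y
        radial = 1.0 + self.k1 * r2 + self.k2 * r2**2 + self.k3 * r2**3
        xd = x * radial + 2 * self.p1 * x * y + self.p2 * (r2 + 2 * x * x)
        yd = y * radial + self.p1 * (r2 + 2 * y * y) + 2 * self.p2 * x * y
        return np.column_stack([xd, yd])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CameraModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PixelScale:
    px_per_mm: float
    source: str = "reference_object"

    def __post_init__(self) -> None:
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


def _object_grid(grid_shape: tuple[int, int], square_size: float) -> np.ndarray:
    """Planar chessboard corner coordinates (x, y, 0), row-major."""
    cols, rows = grid_shape
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    return np.column_stack(
        [xs.ravel() * square_size, ys.ravel() * square_size, np.zeros(cols * rows)]
    )


def _homography(obj_xy: np.ndarray, img_xy: np.ndarray) -> np.ndarray:
    """DLT homography with Hartley normalization."""

    def normalize(pts):
        mean = pts.mean(axis=0)
        scale = np.sqrt(2) / np.mean(np.linalg.norm(pts - mean, axis=1))
        T = np.array([[scale, 0, -scale * mean[0]], [0, scale, -scale * mean[1]], [0, 0, 1]])
        homog = np.column_stack([pts, np.ones(len(pts))])
        return (T @ homog.T).T, T

    src, Ts = normalize(obj_xy)
    dst, Td = normalize(img_xy)
    rows = []
    for (x, y, _), (u, v, _) in zip(src, dst):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, vt = np.linalg.svd(np.asarray(rows))
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _intrinsics_from_homographies(hs: list[np.ndarray]) -> tuple[float, float, float, float]:
    """Closed-form intrinsics (zero skew) from planar homographies."""

    def v_ij(h, i, j):
        return np.array(
            [
                h[0, i] * h[0, j],
                h[0, i] * h[1, j] + h[1, i] * h[0, j],
                h[1, i] * h[1, j],
                h[2, i] * h[0, j] + h[0, i] * h[2, j],
                h[2, i] * h[1, j] + h[1, i] * h[2, j],
                h[2, i] * h[2, j],
            ]
        )

    rows = []
    for h in hs:
        rows.append(v_ij(h, 0, 1))
        rows.append(v_ij(h, 0, 0) - v_ij(h, 1, 1))
    _, _, vt = np.linalg.svd(np.asarray(rows))
    b11, b12, b22, b13, b23, b33 = vt[-1]
    cy = (b12 * b13 - b11 * b23) / (b11 * b22 - b12**2)
    lam = b33 - (b13**2 + cy * (b12 * b13 - b11 * b23)) / b11
    fx = np.sqrt(lam / b11)
    fy = np.sqrt(lam * b11 / (b11 * b22 - b12**2))
    cx = -b13 * fx**2 / lam
    return float(fx), float(fy), float(cx), float(cy)


def _project(params: np.ndarray, obj: np.ndarray, n_views: int) -> np.ndarray:
    fx, fy, cx, cy, k1, k2, k3, p1, p2 = params[:9]
    model = CameraModel(fx, fy, cx, cy, k1, k2, k3, p1, p2)
    out = []
    for v in range(n_views):
        rvec = params[9 + 6 * v : 12 + 6 * v]
        tvec = params[12 + 6 * v : 15 + 6 * v]
        cam = Rotation.from_rotvec(rvec).apply(obj) + tvec
        xy = cam[:, :2] / cam[:, 2:3]
        xyd = model.distort_normalized(xy)
        uv = np.column_stack([fx * xyd[:, 0] + cx, fy * xyd[:, 1] + cy])
        out.append(uv)
    return np.concatenate(out)


def calibrate_camera(
    corner_grids: list[np.ndarray],
    grid_shape: tuple[int, int],
    square_size: float,
) -> CameraModel:
    """Calibrate from detected chessboard corner grids of >= 3 views.

    ``corner_grids`` holds per-view ``(cols*rows, 2)`` arrays of (x, y)
    pixel corner positions in row-major board order; ``grid_shape`` is
    ``(cols, rows)`` of inner corners and ``square_size`` the physical
    square edge (mm).  Returns the model minimizing total reprojection
    error, with its RMS recorded.
    """
    if len(corner_grids) < 3:
        raise CalibrationError("need at least 3 chessboard views")
    n_corners = grid_shape[0] * grid_shape[1]
    for grid in corner_grids:
        if np.asarray(grid).shape != (n_corners, 2):
            raise CalibrationError("corner grid shape inconsistent with grid_shape")
    obj = _object_grid(grid_shape, square_size)
    hs = [_homography(obj[:, :2], np.asarray(g, float)) for g in corner_grids]
    fx, fy, cx, cy = _intrinsics_from_homographies(hs)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1]])
    Kinv = np.linalg.inv(K)

    x0 = [fx, fy, cx, cy, 0.0, 0.0, 0.0, 0.0, 0.0]
    for h in hs:
        a = Kinv @ h
        lam = 1.0 / np.linalg.norm(a[:, 0])
        r1, r2 = lam * a[:, 0], lam * a[:, 1]
        r3 = np.cross(r1, r2)
        R = np.column_stack([r1, r2, r3])
        u, _, vt = np.linalg.svd(R)
        R = u @ vt
        if np.linalg.det(R) < 0:
            R = -R
        t = lam * a[:, 2]
        if t[2] < 0:
            R[:, :2] *= -1
            t = -t
        x0.extend(Rotation.from_matrix(R).as_rotvec())
        x0.extend(t)

    observed = np.concatenate([np.asarray(g, float) for g in corner_grids])

    def residual(params):
        return (_project(params, obj, len(corner_grids)) - observed).ravel()

    sol = least_squares(residual, np.asarray(x0), method="lm", max_nfev=2000)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    fx, fy, cx, cy, k1, k2, k3, p1, p2 = sol.x[:9]
    return CameraModel(fx, fy, cx, cy, k1, k2, k3, p1, p2, reprojection_rms=rms)


def undistort(image: np.ndarray, model: CameraModel, order: int = 1) -> np.ndarray:
    """Resample an image onto the undistorted pixel grid (inverse mapping)."""
    img = np.asarray(image)
    h, w = img.shape[:2]
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    xy = np.column_stack(
        [(uu.ravel() - model.cx) / model.fx, (vv.ravel() - model.cy) / model.fy]
    )
    xyd = model.distort_normalized(xy)
    src_u = model.fx * xyd[:, 0] + model.cx
    src_v = model.fy * xyd[:, 1] + model.cy
    coords = np.vstack([src_v, src_u])

    def sample(channel):
        return ndi.map_coordinates(
            channel.astype(float), coords, order=order, mode="nearest"
        ).reshape(h, w)

    if img.ndim == 2:
        out = sample(img)
    else:
        out = np.stack([sample(img[..., c]) for c in range(img.shape[2])], axis=-1)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def undistort_points(points: np.ndarray, model: CameraModel, iters: int = 20) -> np.ndarray:
    """Map distorted pixel points to their undistorted positions (fixed point)."""
    pts = np.asarray(points, dtype=float)
    xyd = np.column_stack(
        [(pts[:, 0] - model.cx) / model.fx, (pts[:, 1] - model.cy) / model.fy]
    )
    xy = xyd.copy()
    for _ in range(iters):
        delta = model.distort_normalized(xy) - xy
        xy = xyd - delta
    return np.column_stack(
        [model.fx * xy[:, 0] + model.cx, model.fy * xy[:, 1] + model.cy]
    )


def pixel_scale_from_reference(
    reference_mask: np.ndarray,
    known_diameter_mm: float,
    min_circularity: float = 0.9,
) -> PixelScale:
    """Physical pixel scale from a near-circular reference object.

    The scale is the equivalent-circle diameter (from area) divided by the
    known physical diameter.  Rejects empty masks, multi-blob masks, and
    blobs with circularity below ``min_circularity``.
    """
    mask = np.asarray(reference_mask, dtype=bool)
    if known_diameter_mm <= 0:
        raise ValueError("known_diameter_mm must be positive")
    labels, n = ndi.label(mask)
    if n == 0:
        raise CalibrationError("empty reference mask")
    if n > 1:
        sizes = ndi.sum(mask, labels, range(1, n + 1))
        if np.sort(sizes)[-2] > 0.01 * sizes.max():
            raise CalibrationError("reference mask has multiple blobs")
        mask = labels == (1 + int(np.argmax(sizes)))
    area = mask.sum()
    perim = perimeter_of_mask(mask)
    circularity = 4 * np.pi * area / perim**2
    if circularity < min_circularity:
        raise CalibrationError(
            f"reference object circularity {circularity:.3f} below {min_circularity}"
        )
    diameter_px = 2.0 * np.sqrt(area / np.pi)
    return PixelScale(px_per_mm=diameter_px / known_diameter_mm)
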