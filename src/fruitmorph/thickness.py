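"""Kernel thickness prediction from projected area and weight.

A linear (``1, A, W``) or full quadratic (``1, A, W, A², W², A·W``) surface
is fitted by ordinary least squares and validated by repeated random
80/20 train/test splits (100 repetitions by default), reporting the median
test R² and RMSE across repetitions, per-repetition values, and the index
of the best repetition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ThicknessModel", "ValidationSummary", "fit", "validate", "predict"]

_TERMS = {1: ("1", "A", "W"), 2: ("1", "A", "W", "A^2", "W^2", "A*W")}


def _design(area: np.ndarray, weight: np.ndarray, degree: int) -> np.ndarray:
    a = np.asarray(area, dtype=float)
    w = np.asarray(weight, dtype=float)
    cols = [np.ones_like(a), a, w]
    if degree == 2:
        cols += [a**2, w**2, a * w]
    elif degree != 1:
        raise ValueError("degree must be 1 or 2")
    return np.column_stack(cols)


@dataclass
class ThicknessModel:
    degree: int
    coefficients: np.ndarray  # ordered as _TERMS[degree]
    n_train: int
    r2_train: float
    coef_se: np.ndarray | None = None  # OLS standard errors

    def predict(self, area: np.ndarray, weight: np.ndarray) -> np.ndarray:
        return _design(area, weight, self.degree) @ self.coefficients

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "degree": self.degree,
                    "terms": _TERMS[self.degree],
                    "coefficients": self.coefficients.tolist(),
                    "n_train": self.n_train,
                    "r2_train": self.r2_train,
                },
                indent=1,
            )
        )


@dataclass
class ValidationSummary:
    degree: int
    reps: int
    seed: int
    r2_test: np.ndarray  # per repetition
    rmse_test: np.ndarray

    @property
    def median_r2(self) -> float:
        return float(np.median(self.r2_test))

    @property
    def median_rmse(self) -> float:
        return float(np.median(self.rmse_test))

    @property
    def best_rep(self) -> int:
        return int(np.argmax(self.r2_test))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rep": np.arange(self.reps), "r2": self.r2_test, "rmse": self.rmse_test}
        )


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot)


def _columns(data) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return (
            data["area"].to_numpy(float),
            data["weight"].to_numpy(float),
            data["thickness"].to_numpy(float),
        )
    arr = np.asarray(data, dtype=float)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def fit(data, degree: int = 2) -> ThicknessModel:
    """Least-squares fit of thickness on (area, weight).

    ``data`` is a DataFrame with area/weight/thickness columns or an
    ``(n, 3)`` array in that order; needs n >= 10 and a full-rank design.
    """
    area, weight, thickness = _columns(data)
    if len(area) < 10:
        raise ValueError("need at least 10 rows")
    X = _design(area, weight, degree)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    coef, *_ = np.linalg.lstsq(X, thickness, rcond=None)
    resid = thickness - X @ coef
    dof = max(len(area) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return ThicknessModel(
        degree=degree,
        coefficients=coef,
        n_train=len(area),
        r2_train=_r2(thickness, X @ coef),
        coef_se=np.sqrt(np.diag(cov)),
    )


def validate(
    data,
    degree: int = 2,
    train_frac: float = 0.8,
    reps: int = 100,
    seed: int = 0,
) -> ValidationSummary:
    """Repeated random-split validation (deterministic per seed)."""
    area, weight, thickness = _columns(data)
    n = len(area)
    n_test = n - int(round(train_frac * n))
    if n_test < 5:
        raise ValueError("test split smaller than 5 rows")
    rng = np.random.default_rng(seed)
    r2s = np.empty(reps)
    rmses = np.empty(reps)
    frame = pd.DataFrame({"area": area, "weight": weight, "thickness": thickness})
    for rep in range(reps):
        order = rng.permutation(n)
        test = order[:n_test]
        train = order[n_test:]
        model = fit(frame.iloc[train], degree)
        pred = model.predict(area[test], weight[test])
        r2s[rep] = _r2(thickness[test], pred)
        rmses[rep] = float(np.sqrt(np.mean((thickness[test] - pred) ** 2)))
    return ValidationSummary(degree=degree, reps=reps, seed=seed, r2_test=r2s, rmse_test=rmses)


def predict(model: ThicknessModel, area, weight) -> np.ndarray:
    """Evaluate a fitted model (row order has no effect on values)."""
    return model.predict(np.asarray(area, float), np.asarray(weight, float))
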