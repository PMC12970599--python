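"""Broad-sense heritability from genotype × year phenotype tables.

The model is a linear mixed model per trait,

    Y_ijk = mu + G_i + Y_j + e_ijk,

with genotype ``G_i ~ N(0, sigma2_G)`` random, year ``Y_j`` fixed, and
residual ``e_ijk ~ N(0, sigma2_e)``.  Broad-sense heritability is computed
on a per-observation basis,

    H2 = sigma2_G / (sigma2_G + sigma2_e),

without dividing the residual variance by the replicate count (an optional
per-genotype-mean variant is available but off by default).

Estimation is restricted maximum likelihood, profiled over the variance
ratio lambda = sigma2_G / sigma2_e: for a random-intercept grouping the
marginal covariance is block diagonal with blocks ``I + lambda * J``, whose
inverse and log-determinant are closed-form, so the REML criterion is a
cheap 1-D function of lambda maximized numerically.  For balanced designs
the result coincides with the classical expected-mean-squares (ANOVA)
estimator, exposed here as :func:`ems_h2` and used as an independent check.
Negative variance estimates are truncated at zero and flagged as boundary
solutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["HeritabilityResult", "fit_h2", "h2_table", "ems_h2", "plot_h2_bar"]


@dataclass
class HeritabilityResult:
    trait: str
    sigma2_G: float
    sigma2_e: float
    H2: float
    fixed_effects: dict
    n_obs: int
    n_genotypes: int
    converged: bool = True
    boundary: bool = False  # sigma2_G truncated at zero


def _build_design(
    df: pd.DataFrame, value_col: str, genotype_col: str, year_col: str | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    y = df[value_col].to_numpy(float)
    groups, group_idx = np.unique(df[genotype_col].to_numpy(), return_inverse=True)
    names = ["intercept"]
    cols = [np.ones(len(df))]
    if year_col is not None and year_col in df.columns:
        years = np.unique(df[year_col].to_numpy())
        for yr in years[1:]:  # first level is the reference
            cols.append((df[year_col].to_numpy() == yr).astype(float))
            names.append(f"year[{yr}]")
    X = np.column_stack(cols)
    return y, X, group_idx, names


class _RemlStats:
    """Per-group sufficient statistics; make the REML profile O(groups)."""

    def __init__(self, y: np.ndarray, X: np.ndarray, group_idx: np.ndarray):
        self.N, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        n_groups = int(group_idx.max()) + 1
        self.counts = np.bincount(group_idx, minlength=n_groups).astype(float)
        self.Xs = np.zeros((n_groups, self.p))
        for j in range(self.p):
            self.Xs[:, j] = np.bincount(group_idx, weights=X[:, j], minlength=n_groups)
        self.ys = np.bincount(group_idx, weights=y, minlength=n_groups)


def _reml_neg2(lam: float, stats: _RemlStats) -> tuple[float, dict]:
    """-2 REML log-likelihood (up to a constant) at variance ratio lam."""
    shrink = lam / (1.0 + lam * stats.counts)
    XtWX = stats.XtX - (stats.Xs * shrink[:, None]).T @ stats.Xs
    XtWy = stats.Xty - stats.Xs.T @ (shrink * stats.ys)
    ytWy = stats.yty - float(shrink @ stats.ys**2)
    logdet_V = float(np.sum(np.log1p(lam * stats.counts)))
    beta = np.linalg.solve(XtWX, XtWy)
    rss = ytWy - float(beta @ XtWy)
    sigma2_e = rss / (stats.N - stats.p)
    _, logdet_X = np.linalg.slogdet(XtWX)
    crit = (stats.N - stats.p) * np.log(sigma2_e) + logdet_V + logdet_X
    return float(crit), {"beta": beta, "sigma2_e": float(sigma2_e)}


def fit_h2(
    observations: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
    year_col: str | None = "year",
    trait: str | None = None,
) -> HeritabilityResult:
    """REML variance components and H² for one trait.

    ``observations`` is a long-format table with genotype, (optional) year
    and value columns; rows with missing values are dropped.  Requires at
    least 2 genotypes, with replicated genotypes for identifiability.
    """
    cols = [c for c in (genotype_col, year_col, value_col) if c and c in observations.columns]
    df = observations[cols].dropna()
    y, X, group_idx, names = _build_design(df, value_col, genotype_col, year_col)
    n_groups = int(group_idx.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least 2 genotypes")
    counts = np.bincount(group_idx)
    if (counts >= 2).sum() < 2:
        warnings.warn(
            "fewer than 2 genotypes with replicates; variance components are "
            "weakly identified"
        )

    stats = _RemlStats(y, X, group_idx)

    def objective(u: float) -> float:
        return _reml_neg2(np.exp(u), stats)[0]

    # coarse bracket on log-lambda, then refine
    grid = np.linspace(-14.0, 8.0, 45)
    vals = [objective(u) for u in grid]
    u_best = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        objective,
        bounds=(u_best - 1.5, u_best + 1.5),
        method="bounded",
        options={"xatol": 1e-12},
    )
    lam = float(np.exp(res.x))
    crit_opt, aux = _reml_neg2(lam, stats)
    crit_zero, aux_zero = _reml_neg2(0.0, stats)
    boundary = crit_zero <= crit_opt + 1e-10
    if boundary:
        lam, aux = 0.0, aux_zero
    sigma2_e = aux["sigma2_e"]
    sigma2_G = max(lam * sigma2_e, 0.0)
    h2 = sigma2_G / (sigma2_G + sigma2_e) if (sigma2_G + sigma2_e) > 0 else 0.0
    return HeritabilityResult(
        trait=trait or value_col,
        sigma2_G=float(sigma2_G),
        sigma2_e=float(sigma2_e),
        H2=float(h2),
        fixed_effects=dict(zip(names, aux["beta"])),
        n_obs=len(df),
        n_genotypes=n_groups,
        converged=bool(res.success),
        boundary=bool(boundary),
    )


def ems_h2(
    observations: pd.DataFrame,
    value_col: str = "value",
    genotype_col: str = "genotype",
) -> HeritabilityResult:
    """Expected-mean-squares (one-way ANOVA) estimator for balanced designs.

    Method-of-moments: sigma2_G = (MS_between - MS_within) / n0 with n0 the
    per-genotype replicate count (harmonic-mean correction when mildly
    unbalanced).  Serves as the closed-form cross-check for the REML path.
    """
    df = observations[[genotype_col, value_col]].dropna()
    groups = df.groupby(genotype_col)[value_col]
    counts = groups.count().to_numpy(float)
    means = groups.mean().to_numpy(float)
    k = len(counts)
    N = counts.sum()
    grand = df[value_col].mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(
        np.sum((df[value_col] - df.groupby(genotype_col)[value_col].transform("mean")) ** 2)
    )
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - np.sum(counts**2) / N) / (k - 1)
    sigma2_G = max((ms_between - ms_within) / n0, 0.0)
    h2 = sigma2_G / (sigma2_G + ms_within)
    return HeritabilityResult(
        trait=value_col,
        sigma2_G=float(sigma2_G),
        sigma2_e=float(ms_within),
        H2=float(h2),
        fixed_effects={"intercept": float(grand)},
        n_obs=int(N),
        n_genotypes=int(k),
        boundary=bool(ms_between <= ms_within),
    )


def h2_table(
    trait_table: pd.DataFrame,
    genotype_col: str = "genotype",
    year_col: str | None = "year",
    trait_cols: list[str] | None = None,
) -> list[HeritabilityResult]:
    """Heritability for every numeric trait column of a wide table.

    Traits with fewer than 2 genotypes after dropping missing values are
    skipped with a warning.
    """
    if genotype_col not in trait_table.columns:
        raise ValueError(f"missing {genotype_col!r} column")
    if trait_cols is None:
        skip = {genotype_col, year_col, "instance_id"}
        trait_cols = [
            c
            for c in trait_table.select_dtypes(include=[np.number]).columns
            if c not in skip
        ]
    results = []
    for col in trait_cols:
        sub = trait_table[[c for c in (genotype_col, year_col) if c in trait_table.columns] + [col]].dropna()
        if sub[genotype_col].nunique() < 2:
            warnings.warn(f"trait {col!r} has fewer than 2 genotypes; skipped")
            continue
        results.append(
            fit_h2(sub, value_col=col, genotype_col=genotype_col, year_col=year_col, trait=col)
        )
    return results


def plot_h2_bar(results: list[HeritabilityResult], path) -> None:
    """Horizontal bar chart of per-trait heritabilities."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traits = [r.trait for r in results]
    values = [r.H2 for r in results]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(traits))))
    ax.barh(traits, values, color="#7a9e5f")
    ax.set_xlabel("broad-sense heritability $H^2$")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
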