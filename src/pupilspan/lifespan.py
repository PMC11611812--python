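"""Lifespan trajectories: GAM fits, significant periods, sex differences.

Pupil factor scores (and any per-participant measure) are modelled as
smooth functions of age with a Gaussian penalized cubic regression spline
(basis dimension 10, smoothness by REML).  Significant periods of change
are the ages where a 95% simultaneous confidence band for the fit's first
derivative (finite differences, posterior coefficient draws) excludes
zero.  A difference-smooth construction tests for sex differences, and
cross-validated smoothing splines provide the qualitative per-measure,
per-condition age curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from ._pspline import (bspline_design, difference_penalty, fit_penalized,
                       sum_to_zero_constraint)

__all__ = [
    "GamFit", "SexDifferenceResult", "fit_gam", "derivative_significance",
    "smoothing_spline_fit", "sex_difference_window", "bin_age_groups",
    "DEFAULT_AGE_GROUPS",
]

DEFAULT_AGE_GROUPS: list[tuple[float, float]] = [
    (5, 8), (9, 12), (13, 16), (17, 20), (21, 29), (30, 39),
    (40, 49), (50, 59), (60, 69), (70, 83), (84, 93),
]


@dataclass
class GamFit:
    """Smooth age trajectory with derivative-based change periods."""

    grid: np.ndarray               # age grid (200 points)
    fit: np.ndarray
    ci_lo: np.ndarray              # pointwise 95% CI of the fit
    ci_hi: np.ndarray
    deriv: np.ndarray              # first derivative on the grid
    deriv_lo: np.ndarray           # 95% simultaneous band of the derivative
    deriv_hi: np.ndarray
    significant_windows: list[tuple[float, float]]
    basis_dim: int
    lam: float
    edf: float
    scale: float
    coef: np.ndarray = field(repr=False, default=None)
    cov: np.ndarray = field(repr=False, default=None)
    _design_args: tuple = field(repr=False, default=None)


def _runs_to_windows(grid: np.ndarray, mask: np.ndarray
                     ) -> list[tuple[float, float]]:
    windows = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            windows.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return windows


def _simultaneous_crit(draws_dev: np.ndarray, se: np.ndarray,
                       level: float = 0.95) -> float:
    """Critical multiplier for a simultaneous band from posterior draws.

    ``draws_dev`` holds (n_draws, n_grid) deviations of drawn curves from
    the posterior mean; the multiplier is the ``level`` quantile of the
    max absolute standardized deviation across the grid.
    """
    z = np.abs(draws_dev) / se[None, :]
    return float(np.quantile(z.max(axis=1), level))


def fit_gam(age: np.ndarray, y: np.ndarray, k: int = 10,
            grid_n: int = 200, grid_range: tuple[float, float] | None = None,
            n_draws: int = 10_000, seed: int = 0, eps: float = 0.1,
            simultaneous: bool = True, level: float = 0.95,
            min_obs: int = 50) -> GamFit:
    """Penalized-spline GAM of a measure on age, with derivative band.

    Requires at least 50 observations spanning at least 30 years.  The
    derivative is computed by central finite differences (``eps`` years)
    of the fitted smooth; its confidence band is simultaneous across the
    grid by default (a pointwise band is available for comparison).
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.isfinite(age) & np.isfinite(y)
    age, y = age[m], y[m]
    if age.size < min_obs:
        raise ValueError(
            f"need at least {min_obs} observations for a GAM fit")
    lo, hi = (float(age.min()), float(age.max())) \
        if grid_range is None else grid_range
    if hi - lo < 30.0:
        raise ValueError("age span must cover at least 30 years")
    X = bspline_design(age, lo, hi, k=k)
    S = difference_penalty(k)
    res = fit_penalized(X, y, [(slice(0, k), S)])

    grid = np.linspace(lo, hi, grid_n)
    Xg = bspline_design(grid, lo, hi, k=k)
    fit = Xg @ res.coef
    se_fit = np.sqrt(np.einsum("ij,jk,ik->i", Xg, res.cov, Xg))
    z = 1.959963984540054
    # derivative design by central differences, one-sided at the ends
    Xp = bspline_design(np.minimum(grid + eps, hi), lo, hi, k=k)
    Xm = bspline_design(np.maximum(grid - eps, lo), lo, hi, k=k)
    step = np.minimum(grid + eps, hi) - np.maximum(grid - eps, lo)
    Xd = (Xp - Xm) / step[:, None]
    deriv = Xd @ res.coef
    se_d = np.sqrt(np.einsum("ij,jk,ik->i", Xd, res.cov, Xd))
    se_d = np.maximum(se_d, 1e-12)
    if simultaneous:
        rng = np.random.default_rng(seed)
        L = np.linalg.cholesky(res.cov + 1e-12 * np.eye(k))
        draws = rng.standard_normal((n_draws, k)) @ L.T
        crit = _simultaneous_crit(draws @ Xd.T, se_d, level)
    else:
        crit = z
    d_lo = deriv - crit * se_d
    d_hi = deriv + crit * se_d
    windows = _runs_to_windows(grid, (d_lo > 0) | (d_hi < 0))
    return GamFit(
        grid=grid, fit=fit, ci_lo=fit - z * se_fit, ci_hi=fit + z * se_fit,
        deriv=deriv, deriv_lo=d_lo, deriv_hi=d_hi,
        significant_windows=windows, basis_dim=k,
        lam=float(res.lambdas[0]), edf=res.edf, scale=res.scale,
        coef=res.coef, cov=res.cov, _design_args=(lo, hi, k, eps))


def derivative_significance(fit: GamFit) -> list[tuple[float, float]]:
    """Maximal age windows where the derivative band excludes zero."""
    mask = (fit.deriv_lo > 0) | (fit.deriv_hi < 0)
    return _runs_to_windows(fit.grid, mask)


def smoothing_spline_fit(age: np.ndarray, y: np.ndarray,
                         condition: np.ndarray | None = None,
                         grid_n: int = 200
                         ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Cross-validated cubic smoothing spline per condition (QC only).

    Replicate ages are averaged with weights equal to their counts before
    fitting.  Returns ``{condition: (grid, fitted)}``; the single key
    ``"all"`` when no condition labels are given.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    cond = (np.asarray(condition) if condition is not None
            else np.full(age.size, "all"))
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in pd.unique(cond):
        m = (cond == c) & np.isfinite(age) & np.isfinite(y)
        df = pd.DataFrame({"age": age[m], "y": y[m]})
        agg = df.groupby("age")["y"].agg(["mean", "count"]).reset_index()
        x = agg["age"].to_numpy()
        if x.size < 5:
            raise ValueError(f"too few distinct ages for condition {c!r}")
        spline = make_smoothing_spline(
            x, agg["mean"].to_numpy(), w=agg["count"].to_numpy(dtype=float))
        grid = np.linspace(x.min(), x.max(), grid_n)
        out[str(c)] = (grid, spline(grid))
    return out


@dataclass
class SexDifferenceResult:
    grid: np.ndarray
    diff: np.ndarray               # F - M smooth
    diff_lo: np.ndarray            # 95% simultaneous band
    diff_hi: np.ndarray
    significant_windows: list[tuple[float, float]]
    edf: float
    lambdas: np.ndarray


def sex_difference_window(age: np.ndarray, y: np.ndarray,
                          sex: np.ndarray, k: int = 10,
                          grid_n: int = 200, n_draws: int = 10_000,
                          seed: int = 0, level: float = 0.95
                          ) -> SexDifferenceResult:
    """Age windows where female and male trajectories differ.

    Fits a shared age smooth plus a female-specific difference smooth
    (ordered-factor construction): y = a + b*1[F] + f(age) + 1[F]*d(age).
    The reported curve is the total F - M difference b + d(age) with a
    simultaneous 95% band from posterior draws.
    """
    age = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    sex = np.asarray(sex)
    m = np.isfinite(age) & np.isfinite(y)
    age, y, sex = age[m], y[m], sex[m]
    is_f = (sex == "F").astype(float)
    if is_f.min() == is_f.max():
        raise ValueError("both sexes must be present")
    lo, hi = float(age.min()), float(age.max())
    B = bspline_design(age, lo, hi, k=k)
    S = difference_penalty(k)
    Bz, Sz, Z = sum_to_zero_constraint(B, S)
    kz = Bz.shape[1]
    X = np.column_stack([np.ones(age.size), is_f, Bz, Bz * is_f[:, None]])
    blocks = [(slice(2, 2 + kz), Sz), (slice(2 + kz, 2 + 2 * kz), Sz)]
    res = fit_penalized(X, y, blocks)

    grid = np.linspace(lo, hi, grid_n)
    Bg = bspline_design(grid, lo, hi, k=k) @ Z
    # difference curve uses the female dummy plus the difference smooth
    C = np.zeros((grid_n, X.shape[1]))
    C[:, 1] = 1.0
    C[:, 2 + kz:2 + 2 * kz] = Bg
    diff = C @ res.coef
    se = np.sqrt(np.einsum("ij,jk,ik->i", C, res.cov, C))
    se = np.maximum(se, 1e-12)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(res.cov + 1e-12 * np.eye(X.shape[1]))
    draws = rng.standard_normal((n_draws, X.shape[1])) @ L.T
    crit = _simultaneous_crit(draws @ C.T, se, level)
    d_lo = diff - crit * se
    d_hi = diff + crit * se
    windows = _runs_to_windows(grid, (d_lo > 0) | (d_hi < 0))
    return SexDifferenceResult(grid=grid, diff=diff, diff_lo=d_lo,
                               diff_hi=d_hi, significant_windows=windows,
                               edf=res.edf, lambdas=res.lambdas)


def bin_age_groups(ages: np.ndarray,
                   groups: list[tuple[float, float]] | None = None
                   ) -> np.ndarray:
    """Assign each age to one of the (default 11) age groups.

    Boundary ages belong to the lower group (closed-upper convention);
    ages falling in a gap between integer group edges (e.g. 8.4) join the
    group whose upper edge is the next one at or above them.
    """
    if groups is None:
        groups = DEFAULT_AGE_GROUPS
    ages = np.asarray(ages, dtype=float)
    lo = groups[0][0]
    uppers = np.array([g[1] for g in groups], dtype=float)
    if np.any(ages < lo) or np.any(ages > uppers[-1]):
        bad = ages[(ages < lo) | (ages > uppers[-1])][0]
        raise ValueError(f"age {bad} outside the group range "
                         f"[{lo}, {uppers[-1]}]")
    idx = np.searchsorted(uppers, ages, side="left")
    labels = np.array([f"{int(g[0])}-{int(g[1])}" for g in groups])
    return labels[idx]
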