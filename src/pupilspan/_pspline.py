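"""Penalized cubic B-spline regression with REML smoothness selection.

A Gaussian additive smoother: cubic B-spline basis (k functions, equally
spaced knots), second-order difference penalty on the coefficients, and
the smoothing parameter(s) chosen by restricted maximum likelihood.  The
Bayesian posterior covariance of the coefficients supports pointwise and
simultaneous credible bands for the fit and its derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy import optimize

__all__ = ["bspline_design", "difference_penalty", "PenalizedFit",
           "fit_penalized"]


def bspline_design(x: np.ndarray, lo: float, hi: float,
                   k: int = 10, degree: int = 3) -> np.ndarray:
    """Design matrix of ``k`` cubic B-spline basis functions on [lo, hi].

    Knots are equally spaced with the boundary knots repeated; points
    outside [lo, hi] are clipped (basis constant extrapolation is not
    needed for the grids used here).
    """
    if k < degree + 1:
        raise ValueError("k must be at least degree + 1")
    n_inner = k - degree - 1
    inner = np.linspace(lo, hi, n_inner + 2)[1:-1]
    knots = np.concatenate([
        np.repeat(lo, degree + 1), inner, np.repeat(hi, degree + 1)])
    xc = np.clip(np.asarray(x, dtype=float), lo, hi)
    return BSpline.design_matrix(xc, knots, degree).toarray()


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """S = D' D for the ``order``-th difference operator on k coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def sum_to_zero_constraint(B: np.ndarray, S: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reparameterize a smooth so it is orthogonal to the intercept.

    Applies the constraint ``mean(B @ v) = 0`` by restricting the
    coefficients to the null space Z of the basis column means; returns
    the reduced design ``B @ Z``, penalty ``Z' S Z`` and Z itself (for
    evaluating the constrained smooth on new design matrices).
    """
    c = B.mean(axis=0)[None, :]
    # orthonormal null-space basis via full QR of c'
    q, _ = np.linalg.qr(c.T, mode="complete")
    Z = q[:, 1:]
    return B @ Z, Z.T @ S @ Z, Z


@dataclass
class PenalizedFit:
    coef: np.ndarray
    cov: np.ndarray        # Bayesian posterior covariance of coef
    scale: float           # residual variance estimate
    edf: float             # effective degrees of freedom, tr(influence)
    lambdas: np.ndarray    # one per penalty block
    reml: float


def _penalty_embed(n_coef: int, blocks: list[tuple[slice, np.ndarray]],
                   lambdas: np.ndarray) -> np.ndarray:
    P = np.zeros((n_coef, n_coef))
    for (sl, S), lam in zip(blocks, lambdas):
        P[sl, sl] += lam * S
    return P


def _logdet_plus(S: np.ndarray) -> tuple[float, int]:
    """Log pseudo-determinant and rank of a PSD matrix."""
    eig = np.linalg.eigvalsh(S)
    tol = eig.max() * S.shape[0] * np.finfo(float).eps
    pos = eig[eig > tol]
    return float(np.sum(np.log(pos))), int(pos.size)


def fit_penalized(X: np.ndarray, y: np.ndarray,
                  blocks: list[tuple[slice, np.ndarray]],
                  log_lam_bounds: tuple[float, float] = (-10.0, 18.0)
                  ) -> PenalizedFit:
    """Fit y = X b + e with quadratic penalties, lambdas chosen by REML.

    ``blocks`` pairs a coefficient slice with its penalty matrix; each
    block gets its own smoothing parameter.  Penalized blocks must occupy
    disjoint coefficient ranges.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ld_S = []
    ranks = []
    for _, S in blocks:
        ld, r = _logdet_plus(S)
        ld_S.append(ld)
        ranks.append(r)
    mp = q - sum(ranks)   # dimension of the unpenalized (null) space

    def solve(lams: np.ndarray):
        P = _penalty_embed(q, blocks, lams)
        H = XtX + P
        try:
            coef = np.linalg.solve(H, Xty)
        except np.linalg.LinAlgError:
            H = H + 1e-8 * np.eye(q)
            coef = np.linalg.solve(H, Xty)
        rss = yty - 2.0 * coef @ Xty + coef @ XtX @ coef
        pen = coef @ P @ coef
        return coef, H, max(rss, 1e-300), max(rss + pen, 1e-300)

    def reml(log_lams: np.ndarray) -> float:
        lams = np.exp(np.clip(log_lams, *log_lam_bounds))
        coef, H, rss, dp = solve(lams)
        sign, ld_H = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        ld_P = sum(r_ld + np.log(lam) * r
                   for r_ld, lam, r in zip(ld_S, lams, ranks))
        return (n - mp) * np.log(dp) + ld_H - ld_P

    m = len(blocks)
    if m == 1:
        res = optimize.minimize_scalar(
            lambda ll: reml(np.array([ll])), bounds=log_lam_bounds,
            method="bounded", options={"xatol": 1e-3})
        log_opt = np.array([res.x])
    else:
        best = None
        for start in (np.zeros(m), np.full(m, 5.0), np.full(m, -3.0)):
            r = optimize.minimize(reml, start, method="Nelder-Mead",
                                  options={"xatol": 1e-2, "fatol": 1e-4,
                                           "maxiter": 400})
            if best is None or r.fun < best.fun:
                best = r
        log_opt = np.clip(best.x, *log_lam_bounds)
    lams = np.exp(log_opt)
    coef, H, rss, dp = solve(lams)
    # perfect fit (e.g. exactly constant data): REML cannot discriminate
    # between lambdas, so prefer the smoothest equivalent optimum
    if dp <= max(yty, 1.0) * 1e-14:
        hi = np.exp(np.full(m, log_lam_bounds[1]))
        coef_hi, H_hi, rss_hi, dp_hi = solve(hi)
        if rss_hi <= max(yty, 1.0) * 1e-12:
            lams, coef, H, rss, dp = hi, coef_hi, H_hi, rss_hi, dp_hi
            log_opt = np.log(lams)
    Hinv = np.linalg.inv(H)
    edf = float(np.trace(Hinv @ XtX))
    scale = dp / (n - mp)
    cov = scale * Hinv
    return PenalizedFit(coef=coef, cov=cov, scale=float(scale), edf=edf,
                        lambdas=lams, reml=float(reml(log_opt)))
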