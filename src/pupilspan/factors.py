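"""Exploratory factor analysis of pupil and saccade measures.

Sampling adequacy (Kaiser-Meyer-Olkin), Bartlett's test of sphericity,
iterated principal-axis factoring with Kaiser eigenvalue-above-1
retention, direct-oblimin (gamma = 0, i.e. quartimin) oblique rotation via
the gradient-projection algorithm, Thurstone regression factor scores, and
Spearman correlations between pupil and saccade factor scores with
Bonferroni correction.

Factoring runs on the Pearson correlation matrix by default (the
convention of mainstream factor-analysis software); a Spearman matrix can
be requested for display or sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorModel", "FactorCorrelationResult",
    "correlation_matrix", "kmo", "bartlett_sphericity", "choose_n_factors",
    "principal_axis_factoring", "oblimin_rotate", "factor_scores",
    "significant_loadings", "tucker_congruence", "match_factors",
    "factor_factor_correlation", "fit_factor_model",
]


# --------------------------------------------------------------------------
# correlation matrix and adequacy


def correlation_matrix(table: pd.DataFrame,
                       method: str = "pearson") -> pd.DataFrame:
    """Complete-case correlation matrix (symmetric, unit diagonal)."""
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    data = table.dropna()
    if len(data) < 3:
        raise ValueError("need at least 3 complete rows")
    sd = data.std(ddof=1)
    zero = sd[sd == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance column(s): {list(zero.index)}")
    R = data.corr(method=method)
    return (R + R.T) / 2.0


def _as_matrix(R) -> np.ndarray:
    A = np.asarray(R, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("correlation matrix must be square")
    return A


def kmo(R) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy (overall, per variable).

    KMO compares observed correlations r with anti-image partial
    correlations q: sum(r^2) / (sum(r^2) + sum(q^2)) over off-diagonal
    entries; the per-variable analogue restricts the sums to one row.
    """
    A = _as_matrix(R)
    try:
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "correlation matrix is singular; consider removing a "
            "redundant variable") from e
    d = 1.0 / np.sqrt(np.diag(inv))
    Q = -inv * np.outer(d, d)          # partial correlations
    np.fill_diagonal(Q, 0.0)
    R2 = A.copy()
    np.fill_diagonal(R2, 0.0)
    r2 = R2 ** 2
    q2 = Q ** 2
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_var = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), per_var


def bartlett_sphericity(R, n: int) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is identity.

    chi2 = -(n - 1 - (2p + 5) / 6) * ln det(R), df = p (p - 1) / 2.
    """
    A = _as_matrix(R)
    p = A.shape[0]
    if n <= p:
        raise ValueError("sample size must exceed the number of variables")
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("correlation matrix must have positive determinant")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def choose_n_factors(R) -> int:
    """Kaiser criterion: eigenvalues of the full matrix strictly above 1."""
    eig = np.linalg.eigvalsh(_as_matrix(R))
    return int(np.sum(eig > 1.0))


# --------------------------------------------------------------------------
# extraction and rotation


def principal_axis_factoring(R, n_factors: int, max_iter: int = 2000,
                             tol: float = 1e-4
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Iterated principal-axis factoring.

    The diagonal of R is replaced by communality estimates (initialized at
    squared multiple correlations), the reduced matrix is
    eigendecomposed, loadings are eigenvectors scaled by the square root
    of the top eigenvalues, and communalities are updated until the
    largest change falls below ``tol``.  Heywood cases (communality >= 1)
    are clamped to 0.999 with a warning.
    """
    A = _as_matrix(R)
    p = A.shape[0]
    if not 1 <= n_factors < p:
        raise ValueError("n_factors must lie in [1, p)")
    try:
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular") from e
    h2 = 1.0 - 1.0 / np.diag(inv)      # squared multiple correlations
    loadings = np.zeros((p, n_factors))
    for it in range(max_iter):
        red = A.copy()
        np.fill_diagonal(red, h2)
        eigval, eigvec = np.linalg.eigh(red)
        order = np.argsort(eigval)[::-1][:n_factors]
        lam = np.clip(eigval[order], 0.0, None)
        loadings = eigvec[:, order] * np.sqrt(lam)
        new_h2 = np.sum(loadings ** 2, axis=1)
        if np.any(new_h2 >= 1.0):
            warnings.warn("Heywood case: communality clamped to 0.999")
            new_h2 = np.minimum(new_h2, 0.999)
        delta = np.max(np.abs(new_h2 - h2))
        h2 = new_h2
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"principal-axis factoring did not converge in {max_iter} "
            f"iterations (last communality change {delta:.2e})")
    # sign convention: each factor's largest-magnitude loading positive
    for j in range(n_factors):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
    return loadings, h2


def _oblimin_criterion(L: np.ndarray,
                       gamma: float) -> tuple[float, np.ndarray]:
    """Direct-oblimin criterion value and gradient with respect to L."""
    p, k = L.shape
    L2 = L ** 2
    N = np.ones((k, k)) - np.eye(k)
    C = np.eye(p) - (gamma / p) * np.ones((p, p))
    M = C @ L2 @ N
    f = np.sum(L2 * M) / 4.0
    G = L * M
    return f, G


def oblimin_rotate(loadings: np.ndarray, gamma: float = 0.0,
                   max_iter: int = 1000, tol: float = 1e-6
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Direct-oblimin rotation by oblique gradient projection.

    Returns the pattern matrix and the factor correlation matrix.  With
    one factor the rotation is the identity.  Communalities are invariant
    under the (oblique) rotation.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp ** 2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(60):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X ** 2, axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        else:
            break
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    else:
        raise RuntimeError("oblimin rotation did not converge")
    phi = T.T @ T
    # sign convention on rotated factors
    for j in range(k):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
    return L, phi


def factor_scores(table: pd.DataFrame, pattern: np.ndarray,
                  phi: np.ndarray, R=None) -> pd.DataFrame:
    """Thurstone regression factor scores.

    scores = Z R^{-1} S with Z the standardized complete-case data and
    S = pattern @ phi the structure matrix.
    """
    data = table.dropna()
    Z = (data - data.mean()) / data.std(ddof=1)
    if R is None:
        R = np.corrcoef(Z.to_numpy(), rowvar=False)
    A = _as_matrix(R)
    try:
        inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is singular") from e
    S = np.asarray(pattern) @ np.asarray(phi)
    W = inv @ S
    scores = Z.to_numpy() @ W
    cols = [f"factor_{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=data.index, columns=cols)


def significant_loadings(pattern: np.ndarray,
                         threshold: float = 0.3) -> np.ndarray:
    """Mask of loadings whose absolute value strictly exceeds threshold."""
    return np.abs(np.asarray(pattern)) > threshold


# --------------------------------------------------------------------------
# recovery diagnostics


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence (cosine) between two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def match_factors(estimated: np.ndarray, true: np.ndarray
                  ) -> tuple[list[int], list[float], np.ndarray]:
    """Greedily match estimated factors to true factors by |congruence|.

    Returns (permutation, per-factor absolute congruences, sign-aligned
    reordered estimate).
    """
    E = np.asarray(estimated, dtype=float)
    T = np.asarray(true, dtype=float)
    k = T.shape[1]
    C = np.zeros((E.shape[1], k))
    for i in range(E.shape[1]):
        for j in range(k):
            C[i, j] = tucker_congruence(E[:, i], T[:, j])
    perm: list[int] = [-1] * k
    cong: list[float] = [0.0] * k
    used: set[int] = set()
    for _ in range(min(k, E.shape[1])):
        absC = np.abs(C)
        absC[list(used), :] = -1.0
        absC[:, [j for j in range(k) if perm[j] >= 0]] = -1.0
        i, j = np.unravel_index(np.argmax(absC), C.shape)
        perm[j] = int(i)
        cong[j] = float(abs(C[i, j]))
        used.add(int(i))
    aligned = np.zeros_like(T)
    for j in range(k):
        if perm[j] < 0:
            continue
        col = E[:, perm[j]]
        if tucker_congruence(col, T[:, j]) < 0:
            col = -col
        aligned[:, j] = col
    return perm, cong, aligned


# --------------------------------------------------------------------------
# cross-domain factor correlations


@dataclass
class FactorCorrelationResult:
    rho: pd.DataFrame            # pupil factors x saccade factors
    p_values: pd.DataFrame
    significant: pd.DataFrame    # Bonferroni-adjusted flags
    n: int
    n_tests: int
    alpha: float = 0.05


def factor_factor_correlation(pupil_scores: pd.DataFrame,
                              saccade_scores: pd.DataFrame,
                              alpha: float = 0.05
                              ) -> FactorCorrelationResult:
    """Spearman correlations between pupil and saccade factor scores.

    Participants are matched on index; the Bonferroni family is every
    (pupil factor, saccade factor) pair.
    """
    ps = pupil_scores.add_suffix("_pupil")
    ss = saccade_scores.add_suffix("_saccade")
    joined = ps.join(ss, how="inner").dropna()
    if len(joined) < 10:
        raise ValueError("need at least 10 complete matched participants")
    pcols = list(ps.columns)
    scols = list(ss.columns)
    m = len(pcols) * len(scols)
    rho = pd.DataFrame(index=pcols, columns=scols, dtype=float)
    pv = pd.DataFrame(index=pcols, columns=scols, dtype=float)
    for a in pcols:
        for b in scols:
            r, p = stats.spearmanr(joined[a], joined[b])
            rho.loc[a, b] = r
            pv.loc[a, b] = p
    sig = pv < (alpha / m)
    return FactorCorrelationResult(rho=rho, p_values=pv, significant=sig,
                                   n=len(joined), n_tests=m, alpha=alpha)


# --------------------------------------------------------------------------
# orchestration


@dataclass
class FactorModel:
    """Fitted exploratory factor model of one measure table."""

    variables: list[str]
    input_correlation: pd.DataFrame
    kmo_overall: float
    kmo_per_variable: pd.Series
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    eigenvalues: np.ndarray
    n_factors: int
    unrotated_loadings: np.ndarray
    pattern_loadings: np.ndarray
    factor_correlations: np.ndarray
    communalities: np.ndarray
    variance_explained_prerotation: float   # percent
    scores: pd.DataFrame = field(default_factory=pd.DataFrame)


def fit_factor_model(table: pd.DataFrame, n_factors: int | None = None,
                     method: str = "pearson",
                     gamma: float = 0.0) -> FactorModel:
    """Full pipeline: adequacy, extraction, rotation and scoring."""
    data = table.dropna()
    R = correlation_matrix(data, method=method)
    overall, per_var = kmo(R)
    chi2, df, pval = bartlett_sphericity(R, n=len(data))
    eig = np.sort(np.linalg.eigvalsh(R.to_numpy()))[::-1]
    k = choose_n_factors(R) if n_factors is None else int(n_factors)
    k = max(k, 1)
    loadings, h2 = principal_axis_factoring(R.to_numpy(), k)
    pattern, phi = oblimin_rotate(loadings, gamma=gamma)
    var_pct = 100.0 * np.sum(loadings ** 2) / len(R)
    scores = factor_scores(data, pattern, phi, R=R.to_numpy())
    return FactorModel(
        variables=list(R.columns), input_correlation=R,
        kmo_overall=overall,
        kmo_per_variable=pd.Series(per_var, index=R.columns),
        bartlett_chi2=chi2, bartlett_df=df, bartlett_p=pval,
        eigenvalues=eig, n_factors=k, unrotated_loadings=loadings,
        pattern_loadings=pattern, factor_correlations=phi,
        communalities=h2, variance_explained_prerotation=float(var_pct),
        scores=scores)
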