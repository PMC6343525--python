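"""Mixed-model machinery: kinship, REML variance components, GLS scan.

The polygenic model is y ~ N(Xb, sigma_g2 * K + sigma_e2 * I) with K a
genomic relationship matrix from standardized marker calls.  Restricted
maximum likelihood is profiled down to a one-dimensional search over
delta = sigma_e2 / sigma_g2 on the spectral decomposition of K, and the
per-marker scan re-uses the variance components of the current cofactor
model for every candidate (the usual approximation that keeps a scan
linear in the number of markers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from heliastress.genotypes import GenotypeMatrix

__all__ = ["VarianceComponents", "kinship", "reml_variance_components", "gls_scan"]


def kinship(geno: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Genomic relationship matrix K = Z Z' / m from standardized calls.

    ``geno`` is a GenotypeMatrix or a lines x markers float array.
    Missing calls are mean-imputed; zero-variance markers are dropped
    with a warning.  K is symmetric PSD with diagonal mean ~ 1.
    """
    X = geno.imputed() if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("kinship needs at least 2 lines and 2 markers")
    sd = X.std(axis=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} zero-variance marker(s)", stacklevel=2)
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic markers left for kinship")
    Z = (X - X.mean(axis=0)) / sd
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2.0


@dataclass
class VarianceComponents:
    """REML estimates on the spectral decomposition of K."""

    sigma_g2: float
    sigma_e2: float
    pseudo_h2: float
    reml_loglik: float
    flags: tuple[str, ...] = field(default_factory=tuple)
    # spectral cache, reused by the scan
    eigvals: np.ndarray | None = None
    eigvecs: np.ndarray | None = None


def _neg2_reml(log_delta, d, yt, Xt, n, p):
    delta = np.exp(log_delta)
    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    A = Xt.T @ Xw
    b = np.linalg.solve(A, Xw.T @ yt)
    r = yt - Xt @ b
    rss = max(float(r @ (w * r)), 1e-300)  # y = Xb exactly is a valid input
    sign, logdet_A = np.linalg.slogdet(A)
    return (
        (n - p) * np.log(rss / (n - p))
        + np.sum(np.log(d + delta))
        + logdet_A
    )


def reml_variance_components(
    y: np.ndarray,
    K: np.ndarray,
    X: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> VarianceComponents:
    """REML fit of y ~ N(Xb, sigma_g2 K + sigma_e2 I).

    One-dimensional optimization over log delta (delta = sigma_e2 /
    sigma_g2) after eigendecomposition of K; ``eig`` lets callers re-use
    the decomposition across repeated fits on the same K.  Boundary
    optima and an unidentifiable ridge (K proportional to I) are
    flagged, not errors.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    if eig is None:
        d, U = np.linalg.eigh(np.asarray(K, dtype=float))
    else:
        d, U = eig
    if d[0] < -1e-6 * max(1.0, abs(d[-1])):
        raise ValueError(f"K is not PSD: smallest eigenvalue {d[0]:.3e}")
    d = np.clip(d, 0.0, None)

    yt = U.T @ y
    Xt = U.T @ X
    flags = []
    if np.ptp(d) < 1e-8 * max(1.0, abs(d[-1])):
        flags.append("unidentifiable")

    grid = np.linspace(np.log(1e-6), np.log(1e6), 57)
    vals = [_neg2_reml(g, d, yt, Xt, n, p) for g in grid]
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    res = minimize_scalar(
        _neg2_reml, bounds=(lo, hi), args=(d, yt, Xt, n, p), method="bounded"
    )
    log_delta = float(res.x) if res.fun <= vals[i0] else float(grid[i0])
    delta = np.exp(log_delta)
    if log_delta <= grid[0] + 1e-9:
        flags.append("boundary: sigma_e2 -> 0")
    if log_delta >= grid[-1] - 1e-9:
        flags.append("boundary: sigma_g2 -> 0")

    w = 1.0 / (d + delta)
    Xw = Xt * w[:, None]
    b = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ b
    sigma_g2 = float(r @ (w * r)) / (n - p)
    sigma_e2 = sigma_g2 * delta
    if sigma_g2 + sigma_e2 <= 1e-12:
        flags.append("boundary: zero residual variance")
    neg2 = _neg2_reml(log_delta, d, yt, Xt, n, p)
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        pseudo_h2=1.0 / (1.0 + delta),
        reml_loglik=-0.5 * neg2,
        flags=tuple(flags),
        eigvals=d,
        eigvecs=U,
    )


def _gls_transform(vc: VarianceComponents, *arrays):
    """Whiten arrays by V^{-1/2} using the cached spectral decomposition."""
    d, U = vc.eigvals, vc.eigvecs
    sw = 1.0 / np.sqrt(vc.sigma_g2 * d + vc.sigma_e2)
    out = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        ta = U.T @ a
        out.append(ta * (sw[:, None] if ta.ndim == 2 else sw))
    return out


def gls_scan(
    y: np.ndarray,
    K: np.ndarray,
    vc: VarianceComponents,
    X: np.ndarray,
    candidates: np.ndarray,
    collinear_tol: float = 1e-8,
):
    """Per-candidate Wald/F test of a marker fixed effect under GLS.

    ``X`` is the null design (intercept plus cofactors) and
    ``candidates`` a lines x m matrix of marker columns.  The variance
    components of the cofactor model are held fixed for every candidate.
    Candidates collinear with the cofactors get p = 1 and a flag.

    Returns (pvalues, effects, ses, collinear_mask).
    """
    if vc.eigvals is None:
        vc = reml_variance_components(y, K, X)
    ys, Xs, Ms = _gls_transform(vc, y, X, candidates)
    Q, _ = np.linalg.qr(Xs)
    yr = ys - Q @ (Q.T @ ys)
    Mr = Ms - Q @ (Q.T @ Ms)
    mm = np.einsum("ij,ij->j", Mr, Mr)
    scale = np.maximum(np.einsum("ij,ij->j", Ms, Ms), 1.0)
    collinear = mm <= collinear_tol * scale
    my = Mr.T @ yr
    n, p = Xs.shape
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("no residual degrees of freedom for the scan")
    rss0 = float(yr @ yr)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(collinear, 0.0, my / mm)
        rss1 = np.maximum(rss0 - np.where(collinear, 0.0, my**2 / mm), 1e-300)
        F = (rss0 - rss1) * dof / rss1
        se = np.sqrt(rss1 / dof / np.where(collinear, 1.0, mm))
    pvals = stats.f.sf(F, 1, dof)
    pvals = np.where(collinear, 1.0, np.clip(pvals, np.finfo(float).tiny, 1.0))
    return pvals, beta, se, collinear


def joint_gls_fit(y, vc: VarianceComponents, X: np.ndarray):
    """GLS coefficients, SEs and t-test p-values for a joint fixed design."""
    ys, Xs = _gls_transform(vc, y, X)
    n, p = Xs.shape
    coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    r = ys - Xs @ coef
    dof = max(n - p, 1)
    s2 = float(r @ r) / dof
    cov = s2 * np.linalg.inv(Xs.T @ Xs)
    se = np.sqrt(np.diag(cov))
    tstat = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return coef, se, np.clip(pvals, np.finfo(float).tiny, 1.0)
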