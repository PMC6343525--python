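"""Drought response traits estimated from platform dry-down experiments.

Two regressions are implemented:

* the FTSW response curve of a daily process (leaf expansion or
  transpiration), ``r(FTSW; a) = -1 + 2 / (1 + exp(a * FTSW))`` with a
  single negative shape parameter ``a`` — the more negative ``a``, the
  later (at lower FTSW) the genotype starts to down-regulate the process;
* the yield-vs-cumulative-stress "polynomial ratio" model
  ``Y = (a + b*S) / (1 + c*S)`` where S is SFTSW (integrated 1 - FTSW),
  quantified by its relative RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponseCurveFit",
    "YieldResponseFit",
    "eval_ftsw_response",
    "relative_response",
    "fit_ftsw_response",
    "fit_yield_response",
    "rrmse",
    "simulate_response_points",
]

#: admissible box for the response-curve shape parameter
A_BOUNDS = (-30.0, -0.01)


@dataclass(frozen=True)
class ResponseCurveFit:
    """Result of fitting r(FTSW; a) to (ftsw, ratio) points."""

    trait: str
    a_hat: float
    se_a: float
    n_points: int
    residual_sd: float
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class YieldResponseFit:
    """Coefficients of Y = (a + b*S) / (1 + c*S) and its relative RMSE (%)."""

    a: float
    b: float
    c: float
    rrmse_pct: float
    form: str = "ratio"


def eval_ftsw_response(a: float, ftsw):
    """Evaluate the FTSW response curve r = -1 + 2 / (1 + exp(a * ftsw)).

    ``a`` must be strictly negative.  The curve is 0 at FTSW = 0, strictly
    increasing in FTSW, bounded in [0, 1), and decreasing in ``a`` (a more
    negative parameter gives a response closer to 1 at any FTSW > 0).
    """
    a = float(a)
    if not np.isfinite(a) or a >= 0:
        raise ValueError(f"response parameter a must be finite and < 0, got {a}")
    ftsw = np.asarray(ftsw, dtype=float)
    out = -1.0 + 2.0 / (1.0 + np.exp(a * ftsw))
    return float(out) if out.ndim == 0 else out


def relative_response(
    stressed: pd.DataFrame,
    control: pd.DataFrame,
    eps: float = 1e-9,
) -> tuple[pd.DataFrame, int]:
    """Normalize stressed plant-day values by the same-day control mean.

    Parameters
    ----------
    stressed : DataFrame with columns ``plant_id, day, value, ftsw``.
    control : DataFrame with columns ``plant_id, day, value``.
    eps : days whose control mean is <= eps are dropped (and counted).

    Returns
    -------
    (points, n_excluded) where ``points`` has columns
    ``plant_id, day, ratio, ftsw``.
    """
    ctrl_mean = control.groupby("day")["value"].mean()
    days = np.intersect1d(stressed["day"].unique(), ctrl_mean.index)
    if days.size == 0:
        raise ValueError("no overlapping days between stressed and control plants")
    ok_days = ctrl_mean.index[ctrl_mean > eps]
    n_excluded = int(np.setdiff1d(days, ok_days).size)
    sub = stressed[stressed["day"].isin(np.intersect1d(days, ok_days))].copy()
    sub["ratio"] = sub["value"].to_numpy() / ctrl_mean.loc[sub["day"]].to_numpy()
    return sub[["plant_id", "day", "ratio", "ftsw"]].reset_index(drop=True), n_excluded


def _nls_1d(resid_fn, starts, bounds):
    best = None
    for s0 in starts:
        try:
            sol = least_squares(resid_fn, x0=[s0], bounds=([bounds[0]], [bounds[1]]))
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("nonlinear least squares failed from every start")
    return best


def fit_ftsw_response(points: pd.DataFrame, trait: str = "TR") -> ResponseCurveFit:
    """Fit the FTSW response curve to (ftsw, ratio) points.

    Nonlinear least squares over a in [-30, -0.01] with five fixed starts.
    Requires >= 3 points spanning an FTSW range of at least 0.3.  A fit
    pinned at the lower bound is flagged ``no regulation detected`` (the
    ratios never drop below 1 over the observed FTSW range).
    """
    ftsw = np.asarray(points["ftsw"], dtype=float)
    ratio = np.asarray(points["ratio"], dtype=float)
    if ftsw.size < 3:
        raise ValueError("need at least 3 (ratio, ftsw) points")
    if np.ptp(ftsw) < 0.3:
        raise ValueError("points must span an FTSW range of at least 0.3")

    def resid(theta):
        return eval_ftsw_response(theta[0], ftsw) - ratio

    starts = [-25.0, -12.0, -6.0, -3.0, -1.0]
    sol = _nls_1d(resid, starts, A_BOUNDS)
    a_hat = float(sol.x[0])
    n = ftsw.size
    r = sol.fun
    dof = max(n - 1, 1)
    sigma2 = float(r @ r) / dof
    jtj = float((sol.jac[:, 0] ** 2).sum())
    se_a = float(np.sqrt(sigma2 / jtj)) if jtj > 0 else np.inf
    flags = []
    if a_hat <= A_BOUNDS[0] + 1e-6:
        flags.append("no regulation detected")
    if a_hat >= A_BOUNDS[1] - 1e-6:
        flags.append("at upper bound")
    return ResponseCurveFit(
        trait=trait,
        a_hat=a_hat,
        se_a=se_a,
        n_points=n,
        residual_sd=float(np.sqrt(sigma2)),
        flags=tuple(flags),
    )


def rrmse(obs, pred) -> float:
    """Relative RMSE in percent: 100 * sqrt(mean((pred - obs)^2)) / mean(obs)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("obs and pred must be non-empty and of equal length")
    m = obs.mean()
    if m == 0:
        raise ValueError("mean of observations is zero; rRMSE undefined")
    return float(100.0 * np.sqrt(np.mean((pred - obs) ** 2)) / m)


def fit_yield_response(y, s, form: str = "ratio") -> YieldResponseFit:
    """Fit the yield-vs-SFTSW model and report coefficients plus rRMSE.

    ``form="ratio"`` fits Y = (a + b*S) / (1 + c*S) (the default reading of
    the polynomial ratio model); ``form="product"`` fits the product variant
    Y = (a + b*S) * (1 + c*S) for sensitivity checks.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(s, dtype=float)
    if y.size < 4 or y.shape != s.shape:
        raise ValueError("need at least 4 aligned (y, s) pairs")
    if np.any(s < 0):
        raise ValueError("SFTSW values must be non-negative")
    if np.ptp(s) == 0:
        raise ValueError("degenerate SFTSW: all values equal, model unidentifiable")
    if form not in ("ratio", "product"):
        raise ValueError(f"unknown form {form!r}; use 'ratio' or 'product'")

    # linear fit as starting point (c = 0 makes both forms linear in a, b)
    A = np.column_stack([np.ones_like(s), s])
    ab0, *_ = np.linalg.lstsq(A, y, rcond=None)
    smax = s.max()

    def predict(theta):
        a, b, c = theta
        if form == "ratio":
            denom = 1.0 + c * s
            return (a + b * s) / denom
        return (a + b * s) * (1.0 + c * s)

    def resid(theta):
        if form == "ratio" and 1.0 + theta[2] * smax <= 1e-9:
            return np.full_like(y, 1e6)
        return predict(theta) - y

    best = None
    for c0 in (-0.5 / max(smax, 1e-9), 0.0, 0.5 / max(smax, 1e-9)):
        sol = least_squares(resid, x0=[ab0[0], ab0[1], c0])
        if best is None or sol.cost < best.cost:
            best = sol
    a, b, c = (float(v) for v in best.x)
    return YieldResponseFit(a=a, b=b, c=c, rrmse_pct=rrmse(y, predict(best.x)), form=form)


def simulate_response_points(
    a: float,
    ftsw_values,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Synthetic (ftsw, ratio) points from a known response curve.

    Convenience generator for recovery and design-precision experiments:
    ratio = r(ftsw; a) + Gaussian noise.
    """
    ftsw = np.asarray(ftsw_values, dtype=float)
    ratio = eval_ftsw_response(a, ftsw) + rng.normal(0.0, noise_sd, size=ftsw.shape)
    return pd.DataFrame(
        {"plant_id": "sim", "day": np.arange(ftsw.size), "ratio": ratio, "ftsw": ftsw}
    )


def coverage_two_se(a_true: float, fits) -> float:
    """Fraction of fits whose estimate lies within 2 SE of the truth."""
    hits = [abs(f.a_hat - a_true) <= 2.0 * f.se_a for f in fits]
    return float(np.mean(hits))
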