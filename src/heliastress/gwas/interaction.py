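"""Two-stage trait derivation: the plant-level TKW stress-response model.

Stage one of the association chain fits, by ordinary least squares,

    TKW = mu + gamma_i + (beta + alpha_i) * SFTSW + eps

with sum-to-zero constraints on the line intercept deviations gamma_i
and the line slope deviations alpha_i, so beta is the average response
of TKW to cumulative water deficit and alpha_i each line's interaction
deviation.  The per-line estimates alpha_i (interaction effect) and
gamma_i + alpha_i (total genetic effect) become the phenotypes of the
marker scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TraitTable", "fit_interaction_model"]


@dataclass
class TraitTable:
    """Per-line traits from the interaction model (one row per line)."""

    table: pd.DataFrame  # line, alpha_hat, gamma_hat, total_hat, se_alpha
    beta_hat: float
    mu_hat: float
    sigma_hat: float

    def trait(self, which: str) -> pd.Series:
        """Scan phenotype: 'alpha' (interaction) or 'total' (gamma + alpha)."""
        col = {"alpha": "alpha_hat", "total": "total_hat"}[which]
        return self.table.set_index("line")[col]


def _sum_to_zero(n_levels: int, codes: np.ndarray) -> np.ndarray:
    """Sum-to-zero (deviation) coding: n_levels - 1 columns."""
    C = np.zeros((codes.size, n_levels - 1))
    for j in range(n_levels - 1):
        C[codes == j, j] = 1.0
    C[codes == n_levels - 1, :] = -1.0
    return C


def fit_interaction_model(plants: pd.DataFrame) -> TraitTable:
    """Fit the TKW decomposition on a per-plant table.

    ``plants`` needs columns ``line, treatment, sftsw, tkw``.  Lines not
    observed in every treatment are excluded with a warning.  Requires at
    least two distinct SFTSW values overall (otherwise the slopes are
    unidentifiable) and at least two usable lines.
    """
    required = {"line", "treatment", "sftsw", "tkw"}
    if not required.issubset(plants.columns):
        raise ValueError(f"plants table needs columns {sorted(required)}")
    treatments = plants["treatment"].unique()
    by_line = plants.groupby("line")["treatment"].nunique()
    bad = by_line.index[by_line < len(treatments)]
    if len(bad):
        warnings.warn(
            f"excluding {len(bad)} line(s) missing a treatment: "
            f"{', '.join(map(str, bad[:5]))}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
        plants = plants[~plants["line"].isin(bad)]
    lines = np.sort(plants["line"].unique())
    n_l = lines.size
    if n_l < 2:
        raise ValueError("need at least two lines observed in every treatment")
    s = plants["sftsw"].to_numpy(dtype=float)
    if np.unique(s).size < 2:
        raise ValueError("SFTSW constant across all plants: slope unidentifiable")

    codes = pd.Categorical(plants["line"], categories=lines).codes.astype(int)
    G = _sum_to_zero(n_l, codes)
    X = np.column_stack([np.ones_like(s), G, s, G * s[:, None]])
    y = plants["tkw"].to_numpy(dtype=float)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            "check treatment/SFTSW structure"
        )
    theta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta
    dof = max(y.size - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    cov = sigma2 * XtX_inv

    mu_hat = float(theta[0])
    g = theta[1:n_l]
    beta_hat = float(theta[n_l])
    a = theta[n_l + 1:]
    gamma = np.concatenate([g, [-g.sum()]])
    alpha = np.concatenate([a, [-a.sum()]])

    # se(alpha_i): contrast variances; the last level is minus the sum
    alpha_cov = cov[n_l + 1:, n_l + 1:]
    se_alpha = np.sqrt(np.concatenate(
        [np.diag(alpha_cov), [float(np.ones(n_l - 1) @ alpha_cov @ np.ones(n_l - 1))]]
    ))

    table = pd.DataFrame(
        {
            "line": lines,
            "alpha_hat": alpha,
            "gamma_hat": gamma,
            "total_hat": gamma + alpha,
            "se_alpha": se_alpha,
        }
    )
    return TraitTable(
        table=table, beta_hat=beta_hat, mu_hat=mu_hat, sigma_hat=float(np.sqrt(sigma2))
    )
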