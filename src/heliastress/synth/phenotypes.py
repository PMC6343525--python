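"""Per-plant thousand-kernel-weight tables with planted QTL x stress effects.

The generating model mirrors the trait decomposition fitted downstream:

    TKW = mu + gamma_i + (beta + alpha_i) * SFTSW + eps

where gamma_i is the genotypic intercept of line i, beta the average
response of TKW to cumulative water deficit, and alpha_i the line's
interaction (stress-response) deviation.  gamma_i and alpha_i are
assembled additively from planted QTL effects plus polygenic terms drawn
from the marker kinship, then centred so the truth satisfies the same
sum-to-zero constraints the estimator uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heliastress.genotypes import GenotypeMatrix

__all__ = ["QTLSpec", "gen_tkw_phenotypes"]


@dataclass(frozen=True)
class QTLSpec:
    """One planted QTL: marker index plus its effect on alpha and/or gamma."""

    marker_index: int
    effect_on_alpha: float = 0.0
    effect_on_gamma: float = 0.0
    allele_origin: str = "parent2"

    def __post_init__(self):
        if not (np.isfinite(self.effect_on_alpha) and np.isfinite(self.effect_on_gamma)):
            raise ValueError("QTL effects must be finite")
        if self.allele_origin not in ("parent1", "parent2"):
            raise ValueError("allele_origin must be 'parent1' or 'parent2'")


def gen_tkw_phenotypes(
    geno: GenotypeMatrix,
    qtls: list[QTLSpec],
    beta: float = -0.5,
    sftsw_by_treatment: dict[str, float] | None = None,
    reps: int = 4,
    resid_sd: float = 2.0,
    mu: float = 50.0,
    polygenic_sd_gamma: float = 1.5,
    polygenic_sd_alpha: float = 0.03,
    seed: int = 0,
):
    """Simulate the two-treatment TKW trial for every line of the panel.

    Defaults emulate the platform trial the estimator targets: four
    replicates per condition, a well-watered control (SFTSW ~ 0) and a
    constant FTSW = 0.4 deficit held for ~40 days of seed filling
    (SFTSW ~ 24 unitless*days); TKW around 50 g with ~2 g plant-to-plant
    residual spread.  Heritability defaults are stated here, not taken
    from any reported trial.

    Returns (plants, truth): a per-plant frame with columns
    ``line, treatment, sftsw, tkw`` and a truth frame with the centred
    per-line ``gamma`` and ``alpha``.
    """
    if sftsw_by_treatment is None:
        sftsw_by_treatment = {"control": 0.0, "stress": 24.0}
    if any(s < 0 for s in sftsw_by_treatment.values()):
        raise ValueError("SFTSW values must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for q in qtls:
        if not (0 <= q.marker_index < geno.n_markers):
            raise ValueError(
                f"QTL marker index {q.marker_index} out of range "
                f"(panel has {geno.n_markers} markers)"
            )
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    X = geno.imputed()  # lines x markers, het carries the parent2 allele

    gamma = np.zeros(n)
    alpha = np.zeros(n)
    for q in qtls:
        carrier = X[:, q.marker_index]
        if q.allele_origin == "parent1":
            carrier = 1.0 - carrier
        gamma += q.effect_on_gamma * carrier
        alpha += q.effect_on_alpha * carrier

    if polygenic_sd_gamma > 0 or polygenic_sd_alpha > 0:
        Z = X - X.mean(axis=0)
        sd = Z.std(axis=0)
        keep = sd > 0
        if keep.any():
            Z = Z[:, keep] / sd[keep]
            m = Z.shape[1]
            # g = Z u / sqrt(m) has covariance sd^2 * K with K = ZZ'/m
            gamma += polygenic_sd_gamma * (Z @ rng.normal(size=m)) / np.sqrt(m)
            alpha += polygenic_sd_alpha * (Z @ rng.normal(size=m)) / np.sqrt(m)

    gamma -= gamma.mean()
    alpha -= alpha.mean()

    rows = []
    for i, line in enumerate(geno.line_ids):
        for treatment, s in sftsw_by_treatment.items():
            eps = rng.normal(0.0, resid_sd, size=reps) if resid_sd > 0 else np.zeros(reps)
            for r in range(reps):
                rows.append(
                    (line, treatment, s,
                     mu + gamma[i] + (beta + alpha[i]) * s + eps[r])
                )
    plants = pd.DataFrame(rows, columns=["line", "treatment", "sftsw", "tkw"])
    truth = pd.DataFrame({"line": geno.line_ids, "gamma": gamma, "alpha": alpha})
    return plants, truth
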