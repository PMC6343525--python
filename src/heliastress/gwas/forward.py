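"""Forward-stepwise multi-locus scan with the mbonf selection rule.

At each step the variance components of the current cofactor model are
re-estimated by REML, every remaining marker is tested by GLS, and the
smallest-p marker joins the cofactors.  The walk stops when the
polygenic pseudo-heritability of the cofactor model drops below a
threshold (the variance left for markers to explain is then close to
zero) or after ``max_steps``.  The reported model is the largest step at
which every included cofactor passes the Bonferroni threshold 0.05 / m
in the re-estimated joint model (the mbonf criterion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from heliastress.genotypes import GenotypeMatrix
from heliastress.gwas.mixed import (
    VarianceComponents,
    gls_scan,
    joint_gls_fit,
    reml_variance_components,
)

__all__ = ["StepRecord", "MLMMResult", "mlmm_forward", "association_report"]


@dataclass(frozen=True)
class StepRecord:
    step: int
    marker: str
    p_value_at_selection: float
    sigma_g2: float
    sigma_e2: float
    pseudo_h2: float


@dataclass
class MLMMResult:
    steps: list[StepRecord]
    scan_pvalues: list[pd.Series]  # per-step marker -> p map (step 1 first)
    cofactor_pvalues: list[np.ndarray]  # joint-model p of cofactors at each step
    selected_model: list[str]
    marker_ids: list[str]
    criterion: str = "mbonf"
    bonferroni: float = field(default=np.nan)
    stopped: str = ""

    @property
    def selected_indices(self) -> list[int]:
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        return [lookup[m] for m in self.selected_model]


def _marker_order(geno: GenotypeMatrix) -> np.ndarray:
    return np.lexsort((geno.map["pos_bp"].to_numpy(),
                       geno.map["linkage_group"].to_numpy()))


def mlmm_forward(
    y,
    K: np.ndarray,
    geno: GenotypeMatrix,
    max_steps: int = 10,
    h2_stop: float = 0.01,
    alpha: float = 0.05,
) -> MLMMResult:
    """Run the forward-stepwise multi-locus mixed-model scan.

    ``y`` is a line-indexed Series or array aligned with ``geno.line_ids``.
    Ties in the minimum p-value break deterministically by map order
    (linkage_group, pos_bp).
    """
    if geno.n_markers < 2:
        raise ValueError("need at least 2 markers")
    if isinstance(y, pd.Series):
        y = y.reindex(geno.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    n = y.size
    order = _marker_order(geno)
    M = geno.imputed()[:, order]  # lines x markers, map order
    ids = [geno.map["marker"].iloc[i] for i in order]
    m = len(ids)
    bonf = alpha / m
    eig = np.linalg.eigh(np.asarray(K, dtype=float))

    cof: list[int] = []
    steps: list[StepRecord] = []
    scans: list[pd.Series] = []
    cof_pvals: list[np.ndarray] = []
    stopped = ""
    for s in range(max_steps + 1):
        X = np.column_stack([np.ones(n)] + [M[:, j] for j in cof])
        vc = reml_variance_components(y, K, X, eig=eig)
        if cof:
            _, _, jp = joint_gls_fit(y, vc, X)
            cof_pvals.append(jp[1:])
        else:
            cof_pvals.append(np.array([]))
        if s == max_steps:
            stopped = stopped or "max_steps"
            break
        if vc.pseudo_h2 < h2_stop:
            stopped = "h2_stop"
            break
        remaining = [j for j in range(m) if j not in cof]
        pv, beta, se, coll = gls_scan(y, K, vc, X, M[:, remaining])
        full = pd.Series(1.0, index=pd.Index(ids, name="marker"))
        full.iloc[remaining] = pv
        scans.append(full)
        best_local = int(np.argmin(pv))  # first minimum = map-order tie-break
        best = remaining[best_local]
        steps.append(
            StepRecord(
                step=s + 1,
                marker=ids[best],
                p_value_at_selection=float(pv[best_local]),
                sigma_g2=vc.sigma_g2,
                sigma_e2=vc.sigma_e2,
                pseudo_h2=vc.pseudo_h2,
            )
        )
        cof.append(best)

    # mbonf: largest prefix in which every cofactor passes 0.05 / m
    n_sel = 0
    for s in range(len(cof_pvals)):
        if cof_pvals[s].size == 0 or np.all(cof_pvals[s] <= bonf):
            n_sel = s
    selected = [ids[j] for j in cof[:n_sel]]
    return MLMMResult(
        steps=steps,
        scan_pvalues=scans,
        cofactor_pvalues=cof_pvals,
        selected_model=selected,
        marker_ids=ids,
        bonferroni=bonf,
        stopped=stopped or "converged",
    )


def association_report(
    result: MLMMResult,
    geno: GenotypeMatrix,
    y,
    K: np.ndarray,
) -> pd.DataFrame:
    """Final association table: one row per selected marker.

    Effects are the allelic effects of the selected markers re-estimated
    jointly in the final mixed model; ``p_at_selection`` is the scan
    p-value at the step where the marker entered.
    """
    cols = ["marker", "linkage_group", "pos_bp", "effect", "se", "p_at_selection"]
    if not result.selected_model:
        return pd.DataFrame(columns=cols)
    if isinstance(y, pd.Series):
        y = y.reindex(geno.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
    lookup = {mk: i for i, mk in enumerate(geno.map["marker"])}
    idx = [lookup[mk] for mk in result.selected_model]
    M = geno.imputed()[:, idx]
    X = np.column_stack([np.ones(y.size), M])
    vc = reml_variance_components(y, K, X)
    coef, se, _ = joint_gls_fit(y, vc, X)
    p_at = {rec.marker: rec.p_value_at_selection for rec in result.steps}
    rows = []
    for k, mk in enumerate(result.selected_model):
        row = geno.map.iloc[lookup[mk]]
        rows.append(
            (mk, int(row["linkage_group"]), int(row["pos_bp"]),
             float(coef[k + 1]), float(se[k + 1]), p_at[mk])
        )
    return pd.DataFrame(rows, columns=cols)
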