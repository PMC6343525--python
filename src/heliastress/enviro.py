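"""Envirotyping: environment types from simulated stress indicators.

Each environment (location x year) is summarized by the 4-vector of
integrated abiotic-stress indicators (SFTSW, SNNI, SLT, SHT), averaged
over the simulated genotypes.  Environments are classified by principal
components of the standardized indicators followed by Ward hierarchical
clustering (the HCPC recipe); the number of clusters is fixed or chosen
by the largest relative gain of between-cluster inertia.  Clusters are
named after their dominant standardized indicator, genotypes are
profiled by how often they rank first within each environment type, and
locations by how their years distribute over the types.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

__all__ = [
    "INDICATORS",
    "EnvironmentTyping",
    "build_indicator_matrix",
    "cluster_environments",
    "name_clusters",
    "rank_genotypes",
    "location_summary",
]

INDICATORS = ("SFTSW", "SNNI", "SLT", "SHT")

#: indicator -> environment-type name for dominant-stress labelling
STRESS_NAMES = {
    "SFTSW": "Water",
    "SNNI": "Nitrogen",
    "SLT": "LowTemp",
    "SHT": "HighTemp",
}


@dataclass
class EnvironmentTyping:
    labels: pd.Series  # env_id -> cluster id (1..k)
    cluster_names: dict[int, str]
    pc_scores: pd.DataFrame  # environments x retained PCs
    centroids: pd.DataFrame  # cluster x indicator, original scale
    centroids_std: pd.DataFrame  # cluster x indicator, standardized scale

    @property
    def k(self) -> int:
        return int(self.labels.nunique())


def build_indicator_matrix(runs) -> pd.DataFrame:
    """Average per-genotype stress indicators into one row per environment.

    ``runs`` maps (genotype, env_id) -> indicator dict, or is an iterable
    of (genotype, env_id, indicators).  Unbalanced genotype coverage
    across environments triggers a warning listing the gaps.
    """
    if isinstance(runs, dict):
        items = [(g, e, ind) for (g, e), ind in runs.items()]
    else:
        items = list(runs)
    if not items:
        raise ValueError("no simulation runs provided")
    df = pd.DataFrame(
        [{"genotype": g, "env_id": e, **ind} for g, e, ind in items]
    )
    counts = df.groupby("env_id")["genotype"].nunique()
    if counts.nunique() > 1:
        gaps = counts.index[counts < counts.max()].tolist()
        warnings.warn(
            f"unbalanced genotype sets across environments: {gaps[:10]}",
            stacklevel=2,
        )
    mat = df.groupby("env_id")[list(INDICATORS)].mean()
    mat.columns.name = "indicator"
    return mat


def cluster_environments(
    mat: pd.DataFrame,
    k: int | str = "auto",
    var_threshold: float = 0.95,
    k_range: tuple[int, int] = (2, 8),
) -> EnvironmentTyping:
    """PCA + Ward clustering of the indicator matrix.

    Columns are standardized (constant columns dropped with a warning),
    PCs covering ``var_threshold`` of the variance are retained, and Ward
    linkage is cut at ``k`` clusters; ``k="auto"`` picks the cut whose
    relative within-inertia gain is largest over ``k_range``.
    Deterministic given the input row order.
    """
    X = mat.to_numpy(dtype=float)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k_ in zip(mat.columns, keep) if not k_]
        warnings.warn(f"dropping constant indicator column(s): {dropped}", stacklevel=2)
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    n_env = Xs.shape[0]

    pca = PCA()
    scores = pca.fit_transform(Xs)
    n_pc = int(np.searchsorted(np.cumsum(pca.explained_variance_ratio_), var_threshold) + 1)
    n_pc = min(n_pc, scores.shape[1])
    S = scores[:, :n_pc]

    if isinstance(k, str):
        if k != "auto":
            raise ValueError("k must be an integer or 'auto'")
        k = _auto_k(S, k_range)
    k = int(k)
    if not (1 <= k <= n_env):
        raise ValueError(f"k={k} outside 1..{n_env}")
    if k == 1:
        lab = np.ones(n_env, dtype=int)
    else:
        Z = linkage(S, method="ward")
        lab = fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(lab, index=mat.index, name="cluster")

    centroids = mat.groupby(labels).mean()
    cs = pd.DataFrame(Xs, index=mat.index, columns=mat.columns[keep])
    centroids_std = cs.groupby(labels).mean()
    pc_scores = pd.DataFrame(
        S, index=mat.index, columns=[f"PC{i+1}" for i in range(n_pc)]
    )
    typing = EnvironmentTyping(
        labels=labels,
        cluster_names={},
        pc_scores=pc_scores,
        centroids=centroids,
        centroids_std=centroids_std,
    )
    typing.cluster_names = name_clusters(typing)
    return typing


def _within_inertia(S: np.ndarray, lab: np.ndarray) -> float:
    w = 0.0
    for c in np.unique(lab):
        sub = S[lab == c]
        w += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return w


def _auto_k(S: np.ndarray, k_range: tuple[int, int]) -> int:
    """Elbow on within-cluster inertia: largest ratio of successive gains."""
    k_lo, k_hi = k_range
    k_hi = min(k_hi, S.shape[0] - 1)
    Z = linkage(S, method="ward")
    ks = list(range(max(k_lo - 1, 1), k_hi + 2))
    W = {kk: _within_inertia(S, fcluster(Z, t=kk, criterion="maxclust")) for kk in ks}
    best_k, best_ratio = k_lo, -np.inf
    for kk in range(k_lo, k_hi + 1):
        gain = W[kk - 1] - W[kk]
        gain_next = W[kk] - W[kk + 1]
        ratio = gain / max(gain_next, 1e-12)
        if ratio > best_ratio:
            best_k, best_ratio = kk, ratio
    return best_k


def name_clusters(typing: EnvironmentTyping, threshold: float = 0.5) -> dict[int, str]:
    """Name each cluster by its dominant standardized stress indicator.

    A cluster whose largest standardized centroid indicator is below
    ``threshold`` (in SD units) is named Optimal.  When two clusters
    claim the same stress, the one with the larger centroid keeps the
    name and the other falls back to its next-largest indicator (or
    Optimal when nothing else clears the threshold).
    """
    cs = typing.centroids_std
    names: dict[int, str] = {}
    # process clusters by decreasing dominant value so collisions resolve
    # in favour of the stronger claim
    order = cs.max(axis=1).sort_values(ascending=False).index
    taken: set[str] = set()
    for cid in order:
        row = cs.loc[cid].sort_values(ascending=False)
        name = "Optimal"
        for ind, val in row.items():
            if val < threshold:
                break
            candidate = STRESS_NAMES.get(ind, str(ind))
            if candidate not in taken:
                name = candidate
                break
        if name != "Optimal":
            taken.add(name)
        names[int(cid)] = name
    # several sub-threshold clusters may all be Optimal; disambiguate
    optimals = [cid for cid, nm in names.items() if nm == "Optimal"]
    if len(optimals) > 1:
        for i, cid in enumerate(sorted(optimals)[1:], start=2):
            names[cid] = f"Optimal{i}"
    return names


def rank_genotypes(
    yields: pd.DataFrame,
    typing: EnvironmentTyping,
) -> pd.DataFrame:
    """Top-rank frequency of each genotype within each environment type.

    ``yields`` is a genotype x environment matrix.  Yields are first
    standardized by subtracting each genotype's mean over environments;
    within each environment genotypes are ranked on this index (rank 1 =
    best, ties split fractionally), and the per-cluster frequency with
    which each genotype holds rank 1 is reported.  Frequencies sum to 1
    within a cluster.
    """
    missing = yields.columns[yields.isna().any(axis=0)]
    if len(missing):
        warnings.warn(
            f"dropping {len(missing)} environment(s) with missing yields",
            stacklevel=2,
        )
        yields = yields.drop(columns=missing)
    std = yields.sub(yields.mean(axis=1), axis=0)
    top_share = pd.DataFrame(0.0, index=yields.index, columns=yields.columns)
    for env in std.columns:
        col = std[env]
        winners = col.index[col == col.max()]
        top_share.loc[winners, env] = 1.0 / len(winners)

    rows = []
    for cid in sorted(typing.labels.unique()):
        envs = typing.labels.index[typing.labels == cid]
        envs = [e for e in envs if e in top_share.columns]
        if not envs:
            continue
        freq = top_share[envs].sum(axis=1) / len(envs)
        mean_std = std[envs].mean(axis=1)
        for g in yields.index:
            rows.append(
                (cid, typing.cluster_names.get(int(cid), str(cid)), g,
                 float(freq[g]), float(mean_std[g]))
            )
    return pd.DataFrame(
        rows,
        columns=["cluster", "cluster_name", "genotype",
                 "top_rank_frequency", "mean_standardized_yield"],
    )


_ENV_RE = re.compile(r"^(?P<loc>.+)_(?P<year>\d{4})$")


def location_summary(typing: EnvironmentTyping) -> pd.DataFrame:
    """Per-location frequency of each environment type across its years.

    Environment ids must encode location and year as ``<location>_<year>``.
    Rows sum to 1.
    """
    locs = []
    for env in typing.labels.index:
        m = _ENV_RE.match(str(env))
        if m is None:
            raise ValueError(f"unparsable environment label {env!r}")
        locs.append(m.group("loc"))
    df = pd.DataFrame({"location": locs, "cluster": typing.labels.to_numpy()})
    freq = (
        df.groupby("location")["cluster"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    freq.columns = [typing.cluster_names.get(int(c), str(c)) for c in freq.columns]
    return freq
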