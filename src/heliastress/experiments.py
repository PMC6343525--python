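"""Canonical simulation experiments of the analysis chain.

Each function runs one self-contained computational experiment at its
study conditions — pot calibration, demand, trial sizes, marker-panel
geometry, climate archetypes — and returns the measured quantities.
The analysis drivers, the test suite and the acceptance script all call
these so the conditions are defined once.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from heliastress.cropsim import Management, TABLE_GENOTYPES, simulate, stress_indicators
from heliastress.enviro import build_indicator_matrix, cluster_environments, rank_genotypes
from heliastress.gwas import (
    bin_markers,
    fit_interaction_model,
    gls_scan,
    kinship,
    mlmm_forward,
    reml_variance_components,
)
from heliastress.synth import (
    PlantModelTruth,
    QTLSpec,
    gen_climate,
    gen_plant_model,
    gen_ril_panel,
    gen_tkw_phenotypes,
)
from heliastress.traits import coverage_two_se, fit_ftsw_response, simulate_response_points
from heliastress.water import PotCalibration, compute_ftsw, run_scenario

__all__ = [
    "STANDARD_CAL",
    "STRESS_TARGETS",
    "controller_tracking",
    "response_recovery",
    "design_precision",
    "null_scan_pvalues",
    "qtl_step1_rate",
    "mbonf_false_selection_rate",
    "trial_network_design",
    "simulate_trial_network",
    "archetype_recovery",
]

#: 15-L pot calibration used throughout: 18 kg at capacity, 6 kg TTSW
STANDARD_CAL = PotCalibration(w_max=18.0, ttsw=6.0)

#: target FTSW levels of the multi-level dry-down trial
STRESS_TARGETS = (0.2, 0.3, 0.4, 0.6, 0.75, 0.9, 1.0)

#: plant used for controller experiments: a flowering-stage plant
#: transpiring ~1.1 kg/day at full water, fixed leaf area, a_TR from the
#: fast-responding genotype of the simulation panel
CONTROLLER_PLANT = PlantModelTruth(
    genotype_id="controller", a_tr=-9.66, a_le=-4.94,
    demand_scale=1.1, potential_le=0.0, noise_sd_weight=0.0,
)


def controller_tracking(
    targets=STRESS_TARGETS,
    days: int = 20,
    visits_per_day: int = 4,
    settle_days: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the irrigation controller against each target FTSW level.

    Returns one row per target with the worst absolute tracking error of
    the pre-irrigation FTSW after the settling window.
    """
    rows = []
    for tgt in targets:
        truth = replace(CONTROLLER_PLANT, noise_sd_weight=noise_sd)
        pots, status = run_scenario(
            gen_plant_model(truth, seed), tgt, STANDARD_CAL,
            days=days, visits_per_day=visits_per_day,
        )
        pre_f = compute_ftsw(pots.weight_pre, STANDARD_CAL)
        settled = pre_f[settle_days * visits_per_day:]
        rows.append((tgt, float(np.abs(settled - tgt).max()),
                     float(np.abs(status.true_ftsw[settle_days * visits_per_day:] - tgt).max())))
    return pd.DataFrame(rows, columns=["target", "max_abs_error", "max_abs_error_post"])


def response_recovery(
    a_values=(-2.15, -4.94, -9.66, -13.98),
    n_points: int = 60,
    noise_sd: float = 0.05,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Recovery study for the response-curve parameter.

    For each true ``a``: the noise-free recovery error and the fraction
    of noisy replicates whose estimate falls within 2 SE of the truth.
    """
    rng = np.random.default_rng(seed)
    ftsw = np.linspace(0.02, 1.0, n_points)
    rows = []
    for a in a_values:
        clean = fit_ftsw_response(simulate_response_points(a, ftsw, 0.0, rng))
        fits = [
            fit_ftsw_response(simulate_response_points(a, ftsw, noise_sd, rng))
            for _ in range(n_reps)
        ]
        rows.append((a, abs(clean.a_hat - a), coverage_two_se(a, fits)))
    return pd.DataFrame(rows, columns=["a_true", "noise_free_abs_error", "coverage_2se"])


def design_precision(
    a_values=(-4.94, -9.66),
    noise_sd: float = 0.05,
    n_reps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Dense (platform-like) vs sparse (3-visit) sampling of the curve.

    Equal point noise and point count; the daily dry-down covers the
    whole FTSW range down to near-zero, whereas three greenhouse visits
    only catch mid-to-high FTSW before the plants are harvested.
    Returns the mean standard error of the estimated parameter per
    design and genotype.
    """
    rng = np.random.default_rng(seed)
    dense = np.linspace(0.02, 1.0, 30)
    sparse = np.tile(np.array([0.45, 0.7, 1.0]), 10)
    rows = []
    for a in a_values:
        for name, grid in (("dense", dense), ("sparse", sparse)):
            ses = [
                fit_ftsw_response(simulate_response_points(a, grid, noise_sd, rng)).se_a
                for _ in range(n_reps)
            ]
            rows.append((a, name, float(np.mean(ses))))
    return pd.DataFrame(rows, columns=["a_true", "design", "mean_se_a"])


def _simulate_polygenic(rng, n, m, h2):
    """Null trait with polygenic structure: markers, K, y (no QTL)."""
    X = (rng.random((n, m)) < 0.5).astype(float)
    K = kinship(X)
    d, U = np.linalg.eigh(K)
    g = U @ (np.sqrt(np.clip(d, 0, None)) * rng.normal(size=n))
    sg = np.sqrt(h2)
    se = np.sqrt(1.0 - h2)
    y = sg * g + se * rng.normal(size=n)
    return X, K, y


def null_scan_pvalues(
    n_reps: int = 100,
    n: int = 200,
    m: int = 500,
    h2: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Scan p-values under the global null (polygenic trait, no QTL)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        X, K, y = _simulate_polygenic(rng, n, m, h2)
        vc = reml_variance_components(y, K)
        pv, *_ = gls_scan(y, K, vc, np.ones((n, 1)), X)
        out.append(pv)
    return np.concatenate(out)


# panel geometry for the paper-scale interaction-QTL experiment: 17
# linkage groups, ~6.7 cM marker spacing, one planted alpha-QTL whose
# share of the interaction-trait variance is ~50% under the generator's
# default noise (resid 2 g, 4 reps, SFTSW 0 vs 24)
QTL_PANEL = dict(lg_count=17, markers_per_lg=15, dup_fraction=0.1)
QTL_ALPHA_EFFECT = 0.15


def qtl_step1_rate(
    n_reps: int = 50,
    n_lines: int = 90,
    seed: int = 0,
) -> float:
    """End-to-end recovery: fraction of replicates in which the planted
    interaction-QTL's bin is the step-1 selection of the forward scan."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        s = int(rng.integers(2**31 - 1))
        geno, _, _ = gen_ril_panel(n_lines=n_lines, seed=s, **QTL_PANEL)
        qtl_idx = int(rng.integers(geno.n_markers))
        plants, _ = gen_tkw_phenotypes(
            geno, [QTLSpec(qtl_idx, effect_on_alpha=QTL_ALPHA_EFFECT)], seed=s + 1
        )
        traits = fit_interaction_model(plants)
        bins, reps = bin_markers(geno)
        y = traits.trait("alpha")
        K = kinship(reps)
        res = mlmm_forward(y, K, reps, max_steps=1)
        if res.steps:
            planted_bin = bins.iloc[qtl_idx]
            if bins.get(res.steps[0].marker) == planted_bin:
                hits += 1
    return hits / n_reps


def mbonf_false_selection_rate(
    n_reps: int = 100,
    n: int = 200,
    m: int = 500,
    h2: float = 0.5,
    seed: int = 0,
) -> float:
    """Family-wise false selection rate of the mbonf rule on null traits."""
    from heliastress.genotypes import GenotypeMatrix

    rng = np.random.default_rng(seed)
    false = 0
    for _ in range(n_reps):
        X, K, y = _simulate_polygenic(rng, n, m, h2)
        geno = GenotypeMatrix(
            calls=X.T.astype(np.int8),
            map=pd.DataFrame(
                {"marker": [f"S{j}" for j in range(m)],
                 "linkage_group": np.ones(m, dtype=int),
                 "pos_bp": np.arange(m)}
            ),
            line_ids=[f"L{i}" for i in range(n)],
        )
        res = mlmm_forward(y, K, geno, max_steps=5)
        if res.selected_model:
            false += 1
    return false / n_reps


def trial_network_design(
    n_locations: int = 42,
    n_years: int = 21,
    genotypes=TABLE_GENOTYPES,
    seed: int = 0,
) -> pd.DataFrame:
    """Factorial genotype x location x year design of the simulation study.

    Climate is generated for every location-year so the design rows are
    backed by actual inputs; returns one row per simulation unit.
    """
    series, _, _ = gen_climate("optimal", n_years=n_years, n_locations=n_locations, seed=seed)
    rows = [
        (g.name, c.location_id, c.year, c.env_id)
        for c in series
        for g in genotypes
    ]
    return pd.DataFrame(rows, columns=["genotype", "location", "year", "env_id"])


def simulate_trial_network(
    genotypes,
    archetypes=("optimal", "drought", "heat", "cold", "nitrogen"),
    n_locations: int = 5,
    n_years: int = 2,
    seed: int = 0,
):
    """Simulate genotypes across archetype environments.

    Returns (indicator_matrix, yields, labels): the genotype-averaged
    environment x indicator matrix, the genotype x environment yield
    matrix, and the planted archetype label per environment.
    """
    runs, yields, labels_all = {}, {}, {}
    for i, arch in enumerate(archetypes):
        series, soils, labels = gen_climate(
            arch, n_years=n_years, n_locations=n_locations, seed=seed + i
        )
        labels_all.update(labels)
        for c in series:
            for g in genotypes:
                out = simulate(g, c, soils[c.location_id], Management())
                runs[(g.name, c.env_id)] = stress_indicators(out)
                yields[(g.name, c.env_id)] = out.yield_g_m2
    mat = build_indicator_matrix(runs)
    ydf = pd.DataFrame(
        index=[g.name for g in genotypes], columns=mat.index, dtype=float
    )
    for (gname, env), v in yields.items():
        ydf.loc[gname, env] = v
    return mat, ydf, pd.Series(labels_all).loc[mat.index]


def archetype_recovery(
    n_seeds: int = 20,
    n_locations: int = 5,
    n_years: int = 2,
    genotypes=TABLE_GENOTYPES[:2],
    seed: int = 0,
) -> pd.DataFrame:
    """Cluster-recovery study: auto-k clustering vs planted archetypes."""
    rows = []
    for s in range(n_seeds):
        mat, _, labels = simulate_trial_network(
            genotypes, n_locations=n_locations, n_years=n_years, seed=seed + 1000 * s
        )
        typing = cluster_environments(mat, k="auto")
        ari = adjusted_rand_score(labels.to_numpy(), typing.labels.to_numpy())
        rows.append((s, typing.k, float(ari)))
    return pd.DataFrame(rows, columns=["seed", "k", "ari"])
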