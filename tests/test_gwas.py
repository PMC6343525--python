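"""Marker filtering/binning, trait decomposition and the mixed-model scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heliastress.genotypes import MISSING, GenotypeMatrix
from heliastress.gwas import (
    association_report,
    bin_markers,
    filter_markers,
    fit_interaction_model,
    gls_scan,
    kinship,
    mlmm_forward,
    reml_variance_components,
)
from heliastress.synth import QTLSpec, gen_ril_panel, gen_tkw_phenotypes


def toy_geno(calls, lg=None, pos=None):
    calls = np.asarray(calls, dtype=np.int8)
    m = calls.shape[0]
    return GenotypeMatrix(
        calls=calls,
        map=pd.DataFrame(
            {
                "marker": [f"M{i}" for i in range(m)],
                "linkage_group": lg if lg is not None else np.ones(m, dtype=int),
                "pos_bp": pos if pos is not None else np.arange(m),
            }
        ),
        line_ids=[f"L{i}" for i in range(calls.shape[1])],
    )


class TestFilterMarkers:
    def make(self):
        rng = np.random.default_rng(0)
        calls = (rng.random((4, 40)) < 0.5).astype(np.int8)
        calls[1] = (rng.random(40) < 0.35).astype(np.int8)  # freq out of range
        geno = toy_geno(calls)
        parents = pd.DataFrame(
            {"marker": geno.map["marker"],
             "het_or_missing_rate": [0.0, 0.0, 0.15, 0.02]}
        )
        return geno, parents

    def test_rules_and_counts(self):
        geno, parents = self.make()
        kept, report = filter_markers(geno, parents)
        assert report.n_parent_het_missing == 1
        assert "M2" not in kept.map["marker"].tolist()
        assert "M1" not in kept.map["marker"].tolist()
        assert report.n_kept == kept.n_markers

    def test_balanced_clean_marker_kept(self):
        geno, parents = self.make()
        kept, _ = filter_markers(geno, parents)
        assert "M0" in kept.map["marker"].tolist()

    def test_all_rejected_warns_not_raises(self):
        geno, parents = self.make()
        parents["het_or_missing_rate"] = 0.5
        with pytest.warns(UserWarning, match="all markers rejected"):
            kept, report = filter_markers(geno, parents)
        assert kept.n_markers == 0


class TestBinMarkers:
    def test_all_distinct(self):
        geno = toy_geno([[0, 1, 0], [1, 0, 1], [1, 1, 0]])
        bins, reps = bin_markers(geno)
        assert bins.nunique() == 3 and reps.n_markers == 3

    def test_pattern_groups(self):
        A = [0, 1, 1, 0]
        B = [1, 0, 0, 1]
        C = [1, 1, 0, 0]
        geno = toy_geno([A, A, B, C, C])
        bins, reps = bin_markers(geno)
        assert bins.nunique() == 3 and reps.n_markers == 3
        assert bins.iloc[0] == bins.iloc[1] and bins.iloc[3] == bins.iloc[4]

    def test_idempotent_under_duplication(self):
        base = [[0, 1, 1, 0], [1, 0, 0, 1]]
        g1 = toy_geno(base)
        g2 = toy_geno(base + [base[0]])
        assert bin_markers(g1)[0].nunique() == bin_markers(g2)[0].nunique()

    def test_representative_is_leftmost(self):
        geno = toy_geno([[0, 1], [0, 1]], lg=[1, 1], pos=[500, 100])
        _, reps = bin_markers(geno)
        assert reps.map["pos_bp"].iloc[0] == 100

    def test_missing_wildcard_merges(self):
        geno = toy_geno([[0, 1, 1], [0, MISSING, 1]])
        exact, _ = bin_markers(geno)
        wild, _ = bin_markers(geno, missing_wildcard=True)
        assert exact.nunique() == 2 and wild.nunique() == 1


class TestInteractionModel:
    def test_exact_recovery(self, toy_plants):
        fit = fit_interaction_model(toy_plants)
        assert fit.beta_hat == pytest.approx(-0.5, abs=1e-10)
        t = fit.table.set_index("line")
        assert t.loc["L1", "gamma_hat"] == pytest.approx(2.0, abs=1e-10)
        assert t.loc["L1", "alpha_hat"] == pytest.approx(0.1, abs=1e-10)
        assert t.loc["L2", "total_hat"] == pytest.approx(-2.1, abs=1e-10)

    def test_identical_lines_zero_alpha(self):
        rows = []
        for line in ("A", "B", "C"):
            for trt, s in (("c", 0.0), ("s", 24.0)):
                rows.append((line, trt, s, 50.0 - 0.5 * s))
        fit = fit_interaction_model(
            pd.DataFrame(rows, columns=["line", "treatment", "sftsw", "tkw"])
        )
        assert np.allclose(fit.table["alpha_hat"], 0.0, atol=1e-12)

    def test_constant_sftsw_rejected(self, toy_plants):
        bad = toy_plants.assign(sftsw=0.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_interaction_model(bad)

    def test_line_missing_treatment_excluded(self, toy_plants):
        extra = pd.concat(
            [toy_plants,
             pd.DataFrame([("L3", "control", 0.0, 1.0)],
                          columns=["line", "treatment", "sftsw", "tkw"])]
        )
        with pytest.warns(UserWarning, match="missing a treatment"):
            fit = fit_interaction_model(extra)
        assert "L3" not in fit.table["line"].tolist()

    def test_recovery_against_generator_truth(self, small_panel):
        geno = small_panel[0]
        plants, truth = gen_tkw_phenotypes(
            geno, [QTLSpec(5, effect_on_alpha=0.1)], resid_sd=0.0, seed=8
        )
        fit = fit_interaction_model(plants)
        merged = fit.table.merge(truth, on="line")
        assert np.allclose(merged["alpha_hat"], merged["alpha"], atol=1e-8)
        assert np.allclose(merged["gamma_hat"], merged["gamma"], atol=1e-8)


class TestKinship:
    def test_symmetry_and_identical_lines(self):
        rng = np.random.default_rng(0)
        X = (rng.random((40, 200)) < 0.5).astype(float)
        X[1] = X[0]
        K = kinship(X)
        assert np.array_equal(K, K.T)
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)

    def test_unrelated_lines_near_zero(self):
        rng = np.random.default_rng(1)
        X = (rng.random((30, 5000)) < 0.5).astype(float)
        K = kinship(X)
        off = K[~np.eye(30, dtype=bool)]
        assert np.max(np.abs(off)) <= 0.1

    def test_monomorphic_markers_dropped(self):
        rng = np.random.default_rng(2)
        X = (rng.random((10, 20)) < 0.5).astype(float)
        X[:, 3] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            K = kinship(X)
        assert np.all(np.isfinite(K))


class TestReml:
    def simulate(self, rng, n, h2, n_groups=None):
        if n_groups:
            groups = np.repeat(np.arange(n_groups), n // n_groups)
            Z = np.eye(n_groups)[groups]
            K = Z @ Z.T
            g = Z @ rng.normal(size=n_groups)
        else:
            X = (rng.random((n, 400)) < 0.5).astype(float)
            K = kinship(X)
            d, U = np.linalg.eigh(K)
            g = U @ (np.sqrt(np.clip(d, 0, None)) * rng.normal(size=n))
        y = np.sqrt(h2) * g + np.sqrt(1 - h2) * rng.normal(size=n)
        return y, K

    def test_h2_recovery_calibration(self):
        """Pseudo-heritability estimate lands in [0.35, 0.65] for a true
        value of 0.5 in at least 90% of replicates at n = 300."""
        rng = np.random.default_rng(0)
        hits = 0
        reps = 100
        for _ in range(reps):
            y, K = self.simulate(rng, 300, 0.5)
            vc = reml_variance_components(y, K)
            hits += 0.35 <= vc.pseudo_h2 <= 0.65
        assert hits / reps >= 0.90

    def test_noise_free_boundary_flagged(self):
        n = 50
        rng = np.random.default_rng(3)
        K = kinship((rng.random((n, 100)) < 0.5).astype(float))
        y = np.full(n, 2.0)  # y = Xb exactly, intercept-only design
        vc = reml_variance_components(y, K)
        assert vc.sigma_g2 == pytest.approx(0.0, abs=1e-12)
        assert any("boundary" in f for f in vc.flags)

    def test_identity_kinship_ridge_flagged(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=60)
        K = np.eye(60)
        vc = reml_variance_components(y, K)
        assert "unidentifiable" in vc.flags
        # restricted likelihood flat along the ridge
        from heliastress.gwas.mixed import _neg2_reml
        d = np.ones(60)
        yt, Xt = y, np.ones((60, 1))
        lls = [_neg2_reml(g, d, yt, Xt, 60, 1) for g in (-3.0, 0.0, 3.0)]
        assert np.ptp(lls) <= 1e-8

    def test_non_psd_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="not PSD"):
            reml_variance_components(np.array([0.1, -0.2]), K)

    def test_matches_random_intercept_reml(self):
        """Independent oracle: for a block-structured K the model is a
        random-intercept model; compare against statsmodels MixedLM."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n, n_groups = 120, 30
        y, K = self.simulate(rng, n, 0.5, n_groups=n_groups)
        vc = reml_variance_components(y, K)
        groups = np.repeat(np.arange(n_groups), n // n_groups)
        md = sm.MixedLM(y, np.ones((n, 1)), groups=groups).fit(reml=True)
        assert vc.sigma_g2 == pytest.approx(float(np.asarray(md.cov_re)[0, 0]),
                                            rel=1e-3, abs=1e-6)
        assert vc.sigma_e2 == pytest.approx(float(md.scale), rel=1e-3)


def oracle_gls_pvalues(y, K, sigma_g2, sigma_e2, X, M):
    """Direct GLS per candidate: build V, whiten by Cholesky, OLS F-test.

    Written without any shared code with the scan implementation.
    """
    V = sigma_g2 * K + sigma_e2 * np.eye(len(y))
    L = np.linalg.cholesky(V)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    out = []
    for j in range(M.shape[1]):
        mw = np.linalg.solve(L, M[:, j])
        X1 = np.column_stack([Xw, mw])
        b0, res0, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        b1, res1, *_ = np.linalg.lstsq(X1, yw, rcond=None)
        rss0 = float(((yw - Xw @ b0) ** 2).sum())
        rss1 = float(((yw - X1 @ b1) ** 2).sum())
        dof = len(y) - X1.shape[1]
        F = (rss0 - rss1) * dof / rss1
        out.append(stats.f.sf(F, 1, dof))
    return np.array(out)


class TestGlsScan:
    def test_reduces_to_ols_without_polygenic_variance(self):
        rng = np.random.default_rng(0)
        n, m = 40, 15
        M = (rng.random((n, m)) < 0.5).astype(float)
        y = rng.normal(size=n)
        K = kinship(M)
        from heliastress.gwas.mixed import VarianceComponents
        d, U = np.linalg.eigh(K)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0, (), d, U)
        pv, *_ = gls_scan(y, K, vc, np.ones((n, 1)), M)
        ols = oracle_gls_pvalues(y, K, 0.0, 1.0, np.ones((n, 1)), M)
        assert np.max(np.abs(pv - ols) / ols) <= 1e-10

    def test_oracle_equivalence_small_instance(self):
        """Scan p-values match an independent direct GLS implementation
        on a 20-line x 30-marker instance to 1e-8."""
        rng = np.random.default_rng(7)
        n, m = 20, 30
        M = (rng.random((n, m)) < 0.5).astype(float)
        K = kinship(M)
        y = M[:, 4] * 0.5 + rng.normal(size=n)
        vc = reml_variance_components(y, K)
        pv, *_ = gls_scan(y, K, vc, np.ones((n, 1)), M)
        oracle = oracle_gls_pvalues(y, K, vc.sigma_g2, vc.sigma_e2, np.ones((n, 1)), M)
        assert np.max(np.abs(pv - oracle)) <= 1e-8

    def test_collinear_candidate_flagged(self):
        rng = np.random.default_rng(8)
        n = 30
        M = (rng.random((n, 5)) < 0.5).astype(float)
        M[:, 2] = 1.0  # collinear with the intercept
        K = np.eye(n)
        from heliastress.gwas.mixed import VarianceComponents
        d, U = np.linalg.eigh(K)
        vc = VarianceComponents(0.0, 1.0, 0.0, 0.0, (), d, U)
        pv, beta, se, coll = gls_scan(np.random.default_rng(0).normal(size=n),
                                      K, vc, np.ones((n, 1)), M)
        assert coll[2] and pv[2] == 1.0


class TestForward:
    def planted_instance(self, rng, n=200, m=300, frac=0.3):
        M = (rng.random((n, m)) < 0.5).astype(float)
        geno = toy_geno(M.T.astype(np.int8))
        j = 17
        signal = M[:, j] - M[:, j].mean()
        signal /= signal.std()
        noise = rng.normal(size=n)
        y = np.sqrt(frac) * signal + np.sqrt(1 - frac) * noise
        return geno, M, y, j

    def test_strong_qtl_selected_first(self):
        rng = np.random.default_rng(0)
        hits = 0
        reps = 25
        for _ in range(reps):
            geno, M, y, j = self.planted_instance(rng)
            K = kinship(M)
            res = mlmm_forward(y, K, geno, max_steps=1)
            hits += res.steps[0].marker == f"M{j}"
        assert hits / reps >= 0.95

    def test_max_steps_zero_valid_empty(self):
        rng = np.random.default_rng(1)
        geno, M, y, _ = self.planted_instance(rng, n=50, m=20)
        res = mlmm_forward(y, kinship(M), geno, max_steps=0)
        assert res.steps == [] and res.selected_model == []

    def test_report_rows_match_selection_and_effect(self):
        rng = np.random.default_rng(2)
        geno, M, y, j = self.planted_instance(rng, frac=0.4)
        K = kinship(M)
        res = mlmm_forward(y, K, geno, max_steps=3)
        rep = association_report(res, geno, y, K)
        assert len(rep) == len(res.selected_model)
        row = rep[rep.marker == f"M{j}"]
        assert len(row) == 1
        # true per-allele effect of the planted signal
        col = M[:, j]
        truth_eff = np.sqrt(0.4) / col.std()
        assert abs(row["effect"].iloc[0] - truth_eff) <= 2 * row["se"].iloc[0] + 0.05

    def test_empty_selection_empty_report(self):
        rng = np.random.default_rng(3)
        geno, M, y, _ = self.planted_instance(rng, n=60, m=30, frac=0.0)
        K = kinship(M)
        res = mlmm_forward(rng.normal(size=60), K, geno, max_steps=2)
        rep = association_report(res, geno, rng.normal(size=60), K)
        assert len(rep) == len(res.selected_model)

    def test_binning_preserves_scan_minimum(self, small_panel):
        """Scanning bin representatives gives the same per-bin minimum
        p-value as scanning all markers (exact-duplicate redundancy)."""
        geno, _, _ = small_panel
        rng = np.random.default_rng(4)
        bins, reps = bin_markers(geno)
        plants, _ = gen_tkw_phenotypes(geno, [QTLSpec(40, effect_on_alpha=0.15)], seed=5)
        y = fit_interaction_model(plants).trait("alpha")
        yv = y.reindex(geno.line_ids).to_numpy()
        K = kinship(reps)
        vc = reml_variance_components(yv, K)
        pv_all, *_ = gls_scan(yv, K, vc, np.ones((len(yv), 1)), geno.imputed())
        pv_rep, *_ = gls_scan(yv, K, vc, np.ones((len(yv), 1)), reps.imputed())
        pv_all_s = pd.Series(pv_all, index=geno.marker_ids)
        rep_min = pv_all_s.groupby(bins).min()
        rep_ids = reps.marker_ids
        rep_bins = bins[rep_ids].to_numpy()
        assert np.allclose(np.log(pv_rep), np.log(rep_min.loc[rep_bins].to_numpy()),
                           atol=1e-10)
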