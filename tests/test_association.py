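import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from admixscan.association import (
    bh_adjust,
    fit_marker_glm,
    fit_marker_mlm,
    pvalue_cdf_diagnostic,
    run_scan,
    standardized_effect,
)
from admixscan.diversity import filter_by_maf
from admixscan.phenotypes import adjusted_means
from admixscan.structure import estimate_admixture, ritland_kinship

from conftest import matrix_from_calls


def brute_force_bh(p):
    """Step-up definition evaluated literally."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBHAdjust:
    def test_hand_stepup_example(self):
        out = bh_adjust([0.001, 0.01, 0.02, 0.8])
        np.testing.assert_allclose(out, [0.004, 0.02, 0.0266667, 0.8], rtol=1e-5)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw_and_rank_preserving(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-9, 1, rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-14)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_adjust([1.2])


class TestMarkerGLM:
    def test_perfect_fit(self, rng):
        d = rng.integers(0, 3, 50).astype(float)
        res = fit_marker_glm(d.copy(), d)
        assert res["r2_marker"] == pytest.approx(1.0)
        assert res["p_value"] < 1e-30

    def test_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(400):
            d = 2.0 * (rng.random(90) < 0.4)
            y = rng.standard_normal(90)
            if d.var() == 0:
                continue
            ps.append(fit_marker_glm(y, d)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_effect_is_twice_slope(self, rng):
        d = rng.integers(0, 3, 60).astype(float)
        y = 1.5 * d + rng.standard_normal(60)
        res = fit_marker_glm(y, d)
        slope = np.polyfit(d, y, 1)[0]
        assert res["effect"] == pytest.approx(2 * slope, rel=1e-9)

    def test_collinear_marker_flagged(self, rng):
        cov = rng.standard_normal(30)
        res = fit_marker_glm(rng.standard_normal(30), cov, covariates=cov[:, None])
        assert not res["testable"]


class TestMarkerMLM:
    @staticmethod
    def _instance(rng, n=50):
        A = rng.standard_normal((n, n // 2))
        K = A @ A.T / (n // 2) + 0.05 * np.eye(n)
        y = rng.standard_normal(n)
        m = 2.0 * (rng.random(n) < 0.5)
        q = rng.standard_normal((n, 1))
        return y, m, q, K

    @staticmethod
    def _gls_oracle(y, m, q, K, sg2, se2):
        n = y.size
        V = sg2 * K + se2 * np.eye(n)
        Wi = np.linalg.inv(np.linalg.cholesky(V))
        yw = Wi @ y
        X = np.column_stack([np.ones(n), q])
        Xw, mw = Wi @ X, Wi @ m
        Q, _ = np.linalg.qr(Xw)
        ey = yw - Q @ (Q.T @ yw)
        em = mw - Q @ (Q.T @ mw)
        beta = em @ ey / (em @ em)
        rss_red = ey @ ey
        rss_full = rss_red - beta**2 * (em @ em)
        df = n - X.shape[1] - 1
        f = (rss_red - rss_full) / (rss_full / df)
        return stats.f.sf(f, 1, df)

    def test_matches_gls_oracle_with_fixed_components(self, rng):
        for _ in range(30):
            y, m, q, K = self._instance(rng)
            sg2, se2 = rng.uniform(0.2, 2), rng.uniform(0.2, 2)
            res = fit_marker_mlm(y, m, q=q, kinship=K, var_components=(sg2, se2))
            assert res["p_value"] == pytest.approx(
                self._gls_oracle(y, m, q, K, sg2, se2), abs=1e-8)

    def test_zero_genetic_variance_reduces_to_glm(self, rng):
        for _ in range(10):
            y, m, q, K = self._instance(rng)
            mlm = fit_marker_mlm(y, m, q=q, kinship=K, var_components=(0.0, 1.7))
            glm = fit_marker_glm(y, m, covariates=q)
            assert mlm["p_value"] == pytest.approx(glm["p_value"], abs=1e-8)

    def test_identity_kinship_reml_close_to_glm(self, rng):
        y, m, q, _ = self._instance(rng, n=60)
        K = np.eye(60) * 2.0
        mlm = fit_marker_mlm(y, m, q=q, kinship=K, method="p3d")
        glm = fit_marker_glm(y, m, covariates=q)
        # V is proportional to I whatever the split between sg2 and se2
        assert mlm["p_value"] == pytest.approx(glm["p_value"], abs=1e-6)


class TestStandardizedEffect:
    def test_hand_example(self):
        y = np.array([20, 20, 20, 10, 10, 10], float)
        d = np.array([2, 2, 2, 0, 0, 0], float)
        sd = y.std(ddof=1)
        assert standardized_effect(y, d) == pytest.approx(10 / sd)

    def test_identical_class_means_zero(self):
        y = np.array([4.0, 6, 5, 4, 6, 5])
        d = np.array([0.0, 0, 0, 2, 2, 2])
        assert standardized_effect(y, d) == 0.0

    def test_reference_anchoring_flips_sign(self):
        y = np.array([1.0, 1, 2, 9, 9, 8])
        d = np.array([0.0, 0, 0, 2, 2, 2])
        assert standardized_effect(y, d, reference_dosage=2) == pytest.approx(
            -standardized_effect(y, d, reference_dosage=0))

    def test_missing_class_undefined(self):
        y = np.arange(5, dtype=float)
        d = np.array([0.0, 0, 0, 0, 1])
        assert np.isnan(standardized_effect(y, d))

    def test_recovers_planted_effect(self, paper_sim):
        truth = paper_sim.truth["traits"]["LCN"]["qtl"][0]
        g = paper_sim.genotypes
        means = adjusted_means(paper_sim.phenotypes, "LCN").adjusted_series("LCN")
        y = np.log(means.loc[g.accessions].to_numpy())
        d = g.dosage()[:, truth["site_index"]]
        est = standardized_effect(y, d)
        sd = y.std(ddof=1)
        assert abs(abs(est) - abs(2 * truth["effect"]) / sd) < 0.35


class TestRunScan:
    def test_row_count_equals_retained_sites(self, paper_sim):
        g = paper_sim.genotypes
        means = adjusted_means(paper_sim.phenotypes, "FW")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = run_scan(g, means, "FW", model="GLM")
        retained = filter_by_maf(g, 0.05).n_sites
        assert len(tab) == retained

    def test_rerun_is_bit_identical(self, paper_sim):
        g = paper_sim.genotypes
        means = adjusted_means(paper_sim.phenotypes, "LCN")
        t1 = run_scan(g, means, "LCN", model="GLM")
        t2 = run_scan(g, means, "LCN", model="GLM")
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_qtl_is_top_hit_under_kq(self, paper_sim):
        g = paper_sim.genotypes
        gf = filter_by_maf(g, 0.05)
        q = estimate_admixture(gf, 2, seed=17)
        kin = ritland_kinship(gf)
        means = adjusted_means(paper_sim.phenotypes, "LCN")
        tab = run_scan(g, means, "LCN", model="KQ", q=q, kinship=kin,
                       mlm_method="p3d")
        qtl_id = paper_sim.truth["traits"]["LCN"]["qtl"][0]["site_id"]
        assert tab.loc[tab["p_value"].idxmin(), "site_id"] == qtl_id
        row = tab[tab["site_id"] == qtl_id].iloc[0]
        assert row["p_adjusted"] < 0.005
        assert row["significant_a"]

    def test_qtl_marker_r2_estimate_near_truth(self, paper_sim):
        g = paper_sim.genotypes
        gf = filter_by_maf(g, 0.05)
        q = estimate_admixture(gf, 2, seed=17)
        means = adjusted_means(paper_sim.phenotypes, "LCN")
        tab = run_scan(g, means, "LCN", model="Q", q=q)
        truth = paper_sim.truth["traits"]["LCN"]["qtl"][0]
        row = tab[tab["site_id"] == truth["site_id"]].iloc[0]
        assert abs(row["r2_marker"] - truth["realized_r2"]) < 0.12

    def test_empty_scan_warns_with_header(self):
        g = matrix_from_calls(np.zeros((10, 4), dtype=int))
        y = pd.Series(np.arange(10, dtype=float) + 1.0,
                      index=[f"A{i:03d}" for i in range(10)])
        with pytest.warns(UserWarning, match="no testable"):
            tab = run_scan(g, y, "SSC", model="GLM")
        assert len(tab) == 0
        assert "p_adjusted" in tab.columns

    def test_mostly_missing_trait_aborts(self, paper_sim):
        g = paper_sim.genotypes
        y = pd.Series([5.0, 6.0], index=g.accessions[:2])
        with pytest.raises(ValueError, match="missing"):
            run_scan(g, y, "SSC", model="GLM")

    def test_null_scan_rarely_discovers(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(30):
            calls = 2 * (rng.random((60, 100)) < rng.uniform(0.1, 0.9, 100))
            g = matrix_from_calls(calls.astype(int))
            y = pd.Series(rng.standard_normal(60), index=g.accessions)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab = run_scan(g, y, "SSC", model="GLM")
            hits += int((tab["p_adjusted"] < 0.05).any())
        assert hits <= 5  # BH controls family FDR at 5%


class TestCalibrationDiagnostic:
    def test_uniform_pvalues_small_deviation(self, rng):
        diag = pvalue_cdf_diagnostic({"null": rng.uniform(0, 1, 5000)})[0]
        assert diag.max_deviation < 0.03

    def test_ecdf_monotone_and_bounded(self, rng):
        diag = pvalue_cdf_diagnostic({"m": rng.uniform(0, 1, 100)})[0]
        assert np.all(np.diff(diag.ecdf) >= 0)
        assert 0 <= diag.max_deviation <= 1

    def test_structure_confounding_ranks_models(self):
        """K+Q calibrates the confounded null better than Q, which beats GLM."""
        rng = np.random.default_rng(8)
        order_ok = 0
        for rep in range(5):
            n, L = 90, 200
            pool = np.repeat([0, 1], [45, 45])
            p = rng.uniform(0.05, 0.95, L)
            sh = (1 - 0.3) / 0.3
            pf = np.stack([rng.beta(p * sh, (1 - p) * sh) for _ in range(2)])
            G = 2.0 * (rng.random((n, L)) < pf[pool])
            y = 1.0 * pool + rng.standard_normal(n)
            kin = ritland_kinship(G)
            qcov = pool.astype(float)[:, None]
            pvals = {"GLM": [], "Q": [], "KQ": []}
            vc = None
            for j in range(L):
                m = G[:, j]
                if m.var() == 0:
                    continue
                pvals["GLM"].append(fit_marker_glm(y, m)["p_value"])
                pvals["Q"].append(fit_marker_glm(y, m, covariates=qcov)["p_value"])
                res = fit_marker_mlm(y, m, q=qcov, kinship=kin, method="p3d",
                                     var_components=vc)
                vc = (res["sigma_g2"], res["sigma_e2"])
                pvals["KQ"].append(res["p_value"])
            diags = pvalue_cdf_diagnostic(pvals)
            ranked = [d.model for d in diags]
            order_ok += ranked[-1] == "GLM" and ranked[0] in ("KQ", "Q")
        assert order_ok >= 4
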