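import numpy as np
import pandas as pd
import pytest

from admixscan.datatypes import MISSING
from admixscan.ld import (
    DecayFit,
    LDDecayModel,
    fit_ld_decay,
    hotspot_ratio_scan,
    ld_matrix,
    pairwise_r2,
    permutation_pvalue,
    predict_decay,
)

from conftest import make_sites, matrix_from_calls


def haplotype_r2(dosage_a, dosage_b):
    """Independent oracle: haplotype-count r^2 = D^2/(pA pa pB pb) on fully
    homozygous data read as one haplotype per accession."""
    ha = np.asarray(dosage_a) / 2
    hb = np.asarray(dosage_b) / 2
    pa, pb = ha.mean(), hb.mean()
    d = np.mean(ha * hb) - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


class TestPairwiseR2:
    def test_identical_vectors_give_one(self):
        calls = np.array([[0, 0], [2, 2], [0, 0], [2, 2], [2, 2]])
        rec = pairwise_r2(matrix_from_calls(calls), "S000", "S001")
        assert rec.r2 == pytest.approx(1.0)

    def test_hand_haplotype_counts(self):
        # AB=40, ab=40, Ab=10, aB=10 as homozygotes: D = 0.15,
        # r2 = 0.0225/0.0625 = 0.36
        col_a = [2] * 40 + [0] * 40 + [2] * 10 + [0] * 10
        col_b = [2] * 40 + [0] * 40 + [0] * 10 + [2] * 10
        g = matrix_from_calls(np.column_stack([col_a, col_b]))
        rec = pairwise_r2(g, "S000", "S001")
        assert rec.r2 == pytest.approx(0.36, abs=1e-12)

    def test_equals_haplotype_oracle_on_homozygous_data(self, rng):
        for _ in range(200):
            n = rng.integers(6, 40)
            a = 2 * (rng.random(n) < rng.uniform(0.1, 0.9)).astype(int)
            b = 2 * (rng.random(n) < rng.uniform(0.1, 0.9)).astype(int)
            if a.var() == 0 or b.var() == 0:
                continue
            g = matrix_from_calls(np.column_stack([a, b]))
            rec = pairwise_r2(g, "S000", "S001")
            assert rec.r2 == pytest.approx(haplotype_r2(a, b), abs=1e-12)

    def test_symmetric_and_relabel_invariant(self):
        calls = np.array([[0, 2], [2, 0], [2, 2], [0, 0], [2, 0], [0, 2]])
        g = matrix_from_calls(calls)
        r_ab = pairwise_r2(g, "S000", "S001").r2
        r_ba = pairwise_r2(g, "S001", "S000").r2
        flipped = matrix_from_calls(np.column_stack([2 - calls[:, 0], calls[:, 1]]))
        r_flip = pairwise_r2(flipped, "S000", "S001").r2
        assert r_ab == pytest.approx(r_ba) == pytest.approx(r_flip)

    def test_monomorphic_pair_errors(self):
        calls = np.array([[0, 0], [0, 2], [0, 0], [0, 2]])
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_r2(matrix_from_calls(calls), "S000", "S001")

    def test_missing_pairwise_exclusion(self):
        calls = np.array([[0, 0], [2, 2], [0, 0], [2, 2], [MISSING, 2], [2, MISSING]])
        rec = pairwise_r2(matrix_from_calls(calls), "S000", "S001")
        assert rec.n_used == 4
        assert rec.r2 == pytest.approx(1.0)


class TestPermutation:
    def test_perfect_ld_gives_add_one_floor(self):
        rngl = np.random.default_rng(0)
        col = 2 * (rngl.random(20) < 0.5).astype(int)
        while col.var() == 0:
            col = 2 * (rngl.random(20) < 0.5).astype(int)
        g = matrix_from_calls(np.column_stack([col, col]))
        p = permutation_pvalue(g, "S000", "S001", n_perm=1000, seed=1)
        # observed r2 = 1; permutations of a non-constant vector cannot all
        # reproduce it, but ties are possible; p stays near the 1/1001 floor
        assert p <= 5 / 1001

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = []
        for i in range(60):
            a = 2 * (rng.random(30) < 0.5).astype(int)
            b = 2 * (rng.random(30) < 0.5).astype(int)
            if a.var() == 0 or b.var() == 0:
                continue
            g = matrix_from_calls(np.column_stack([a, b]))
            ps.append(permutation_pvalue(g, "S000", "S001", n_perm=200, seed=i))
        assert 0.35 < np.mean(ps) < 0.65

    def test_n_perm_floor(self):
        g = matrix_from_calls(np.array([[0, 0], [2, 2], [0, 2], [2, 0]]))
        with pytest.raises(ValueError):
            permutation_pvalue(g, "S000", "S001", n_perm=10)


class TestLDMatrix:
    def test_pair_count(self):
        calls = np.array([[0, 0, 2, 2], [2, 2, 0, 0], [0, 2, 0, 2], [2, 0, 2, 0]])
        g = matrix_from_calls(calls)
        assert len(ld_matrix(g, maf_threshold=None)) == 6

    def test_one_per_fragment(self):
        frags = ["f1", "f1", "f1", "f2", "f2"]
        rngl = np.random.default_rng(3)
        calls = 2 * (rngl.random((12, 5)) < 0.5).astype(int)
        g = matrix_from_calls(calls, fragments=frags)
        recs = ld_matrix(g, mode="one_per_fragment", maf_threshold=None)
        assert len(recs) == 1

    def test_representative_has_max_heterozygosity(self):
        # fragment f1: site0 MAF 0.1, site1 MAF 0.5 -> site1 representative
        col0 = [2] + [0] * 9
        col1 = [2] * 5 + [0] * 5
        col2 = [2] * 3 + [0] * 7  # fragment f2
        g = matrix_from_calls(np.column_stack([col0, col1, col2]),
                              fragments=["f1", "f1", "f2"])
        recs = ld_matrix(g, mode="one_per_fragment", maf_threshold=None)
        assert set([recs.site_a.iloc[0], recs.site_b.iloc[0]]) == {"S001", "S002"}

    def test_matches_double_loop_oracle(self, tiny_sim):
        g = tiny_sim.genotypes
        table = ld_matrix(g, maf_threshold=0.05)
        got = {(r.site_a, r.site_b): r.r2 for r in table.itertuples()}
        from admixscan.diversity import filter_by_maf

        gf = filter_by_maf(g, 0.05)
        checked = 0
        for ja in range(gf.n_sites):
            for jb in range(ja + 1, gf.n_sites):
                a = gf.calls[:, ja]
                b = gf.calls[:, jb]
                ok = (a != MISSING) & (b != MISSING)
                af, bf = a[ok].astype(float), b[ok].astype(float)
                if ok.sum() < 4 or af.var() == 0 or bf.var() == 0:
                    continue
                key = (gf.sites[ja].site_id, gf.sites[jb].site_id)
                r = np.corrcoef(af, bf)[0, 1] ** 2
                assert got[key] == pytest.approx(r, abs=1e-12)
                checked += 1
        assert checked == len(table)


class TestDecayModel:
    def test_noiseless_recovery(self):
        x = np.linspace(0.05, 10, 200)
        y = 0.1 + 0.8 * np.exp(-2.0 * x)
        model = LDDecayModel().fit(x, y)
        assert model.converged_
        assert model.a_ == pytest.approx(0.1, abs=1e-6)
        assert model.b_ == pytest.approx(0.8, abs=1e-6)
        assert model.c_ == pytest.approx(2.0, abs=1e-5)

    def test_all_distances_equal_rejected(self):
        with pytest.raises(ValueError, match="distances"):
            LDDecayModel().fit(np.full(20, 2.0), np.random.default_rng(0).random(20))

    def test_multistart_sse_nonincreasing(self, rng):
        x = rng.uniform(0.05, 10, 300)
        y = 0.1 + 0.8 * np.exp(-2.0 * x) + rng.normal(0, 0.08, 300)
        sse1 = LDDecayModel(n_starts=1).fit(x, y).residual_sse_
        sse8 = LDDecayModel(n_starts=8).fit(x, y).residual_sse_
        assert sse8 <= sse1 + 1e-12

    def test_predict_limits(self):
        fit = DecayFit(a=0.1, b=0.8, c=2.0, distance_unit="cM",
                       residual_sse=0.0, n_pairs=10, converged=True)
        assert predict_decay(fit, [1e9])[0] == pytest.approx(0.1)
        assert predict_decay(fit, [1e-9])[0] == pytest.approx(0.9)

    def test_predict_rejects_nonpositive_distance(self):
        fit = DecayFit(0.1, 0.8, 2.0, "cM", 0.0, 10, True)
        with pytest.raises(ValueError):
            predict_decay(fit, [0.0])

    def test_predict_matches_formula_on_grid(self, paper_sim):
        pairs = ld_matrix(paper_sim.genotypes, subset="cerasiforme",
                          maf_threshold=0.05)
        fit = fit_ld_decay(pairs[pairs["d_cm"] > 0], "cM")
        xs = np.geomspace(0.1, 50, 20)
        np.testing.assert_allclose(
            predict_decay(fit, xs), fit.a + fit.b * np.exp(-fit.c * xs))

    def test_fitted_curve_is_decreasing(self, paper_sim):
        pairs = ld_matrix(paper_sim.genotypes, subset="cerasiforme",
                          maf_threshold=0.05)
        fit = fit_ld_decay(pairs[pairs["d_cm"] > 0], "cM")
        xs = np.linspace(0.1, 60, 50)
        assert np.all(np.diff(predict_decay(fit, xs)) <= 0)


class TestHotspotScan:
    def test_known_ratios(self):
        sites = make_sites(3, cm=[0.0, 1.0, 2.0], bp=[1, 136001, 156001])
        table = hotspot_ratio_scan(sites, threshold=100.0)
        assert table["kb_per_cm"].tolist() == pytest.approx([136.0, 20.0])
        assert table["candidate_hotspot"].tolist() == [False, True]

    def test_uniform_map_constant_ratio(self):
        sites = make_sites(5, cm=[0, 1, 2, 3, 4], bp=[1, 750001, 1500001, 2250001, 3000001])
        table = hotspot_ratio_scan(sites)
        assert np.allclose(table["kb_per_cm"], 750.0)

    def test_unsorted_input_rejected(self):
        sites = make_sites(3, cm=[1.0, 0.5, 2.0], bp=[1, 1000, 2000])
        with pytest.raises(ValueError, match="sorted"):
            hotspot_ratio_scan(sites)

    def test_zero_cm_interval_flagged_unbounded(self):
        sites = make_sites(2, cm=[1.0, 1.0], bp=[1, 5000])
        table = hotspot_ratio_scan(sites)
        assert table["unbounded"].iloc[0]
        assert np.isinf(table["kb_per_cm"].iloc[0])
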