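import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixscan.datatypes import MISSING
from admixscan.diversity import (
    classify_shared_polymorphisms,
    filter_by_maf,
    harmonic_number,
    maf_spectrum,
    minor_allele_frequency,
    polymorphism_rates,
    singleton_count,
    site_mafs,
    watterson_theta,
)

from conftest import matrix_from_calls


class TestMAF:
    @pytest.mark.parametrize("calls,expected", [
        ([[0], [0], [2], [2], [2]], 0.4),   # alt f = 0.6
        ([[0], [0], [0], [0]], 0.0),
        ([[0], [1], [2], [MISSING]], 0.5),  # missing excluded: 3/6
    ])
    def test_hand_counts(self, calls, expected):
        g = matrix_from_calls(calls)
        assert minor_allele_frequency(g, "S000") == pytest.approx(expected)

    def test_all_missing_site_errors(self):
        g = matrix_from_calls([[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="missing"):
            minor_allele_frequency(g, "S000")

    @given(st.lists(st.integers(0, 2), min_size=2, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_allele_relabel(self, column):
        g = matrix_from_calls([[c] for c in column])
        flipped = matrix_from_calls([[2 - c] for c in column])
        assert minor_allele_frequency(g, "S000") == pytest.approx(
            minor_allele_frequency(flipped, "S000"))


class TestMAFFilter:
    def test_boundary_is_strict(self):
        # one het among 10 accessions: alt f = 1/20 = 0.05 exactly
        calls = np.zeros((10, 1), dtype=int)
        calls[0, 0] = 1
        g = matrix_from_calls(calls)
        assert filter_by_maf(g, 0.05).n_sites == 0
        assert filter_by_maf(g, 0.049).n_sites == 1

    def test_threshold_zero_drops_only_monomorphic(self):
        g = matrix_from_calls([[0, 0, 2], [0, 2, 2], [0, 0, 2]])
        kept = filter_by_maf(g, 0.0)
        assert kept.site_ids == ["S001"]

    def test_idempotent(self, paper_sim):
        once = filter_by_maf(paper_sim.genotypes, 0.05)
        twice = filter_by_maf(once, 0.05)
        assert once == twice

    def test_matches_brute_force_recount(self, paper_sim):
        g = paper_sim.genotypes
        kept = filter_by_maf(g, 0.05)
        expected = 0
        for j in range(g.n_sites):
            col = g.calls[:, j]
            col = col[col != MISSING]
            f = col.sum() / (2 * len(col))
            if min(f, 1 - f) > 0.05:
                expected += 1
        assert kept.n_sites == expected


class TestWatterson:
    def test_monomorphic_theta_zero(self):
        g = matrix_from_calls(np.zeros((5, 4), dtype=int))
        theta, s = watterson_theta(g, total_length=1000)
        assert theta == 0 and s == 0

    def test_known_harmonic_evaluation(self):
        # n=10, S=7, L=1000: a_9 evaluated independently
        calls = np.zeros((10, 10), dtype=int)
        calls[0, :7] = 2  # 7 polymorphic sites
        g = matrix_from_calls(calls)
        theta, s = watterson_theta(g, total_length=1000)
        a9 = sum(1.0 / i for i in range(1, 10))
        assert s == 7
        assert theta == pytest.approx(7 / (a9 * 1000), rel=1e-12)
        assert a9 == pytest.approx(2.828968, abs=1e-6)

    def test_harmonic_number_closed_form(self):
        assert harmonic_number(2) == 1.0
        assert harmonic_number(5) == pytest.approx(1 + 0.5 + 1 / 3 + 0.25)

    def test_subset_too_small(self):
        g = matrix_from_calls([[0], [2]])
        with pytest.raises(ValueError):
            watterson_theta(g, subset=np.array([True, False]))

    def test_invariant_under_allele_relabel(self, tiny_sim):
        g = tiny_sim.genotypes
        flipped = matrix_from_calls(
            np.where(g.calls == MISSING, MISSING, 2 - g.calls))
        assert watterson_theta(g, total_length=100)[0] == pytest.approx(
            watterson_theta(flipped, total_length=100)[0])


class TestRatesAndSharing:
    def test_rate_per_kb(self):
        region = ["coding"] * 10 + ["noncoding"] * 3
        calls = np.zeros((6, 13), dtype=int)
        calls[0, :10] = 2  # 10 coding polymorphisms
        g = matrix_from_calls(calls, region=region)
        rates = polymorphism_rates(g, coding_length=5000, noncoding_length=1000)
        assert rates["rate_coding"] == pytest.approx(2.0)
        assert rates["rate_noncoding"] == 0.0

    def test_equal_rates_give_unit_ratio(self):
        region = ["coding", "noncoding"]
        calls = np.array([[0, 0], [2, 2], [0, 0]])
        g = matrix_from_calls(calls, region=region)
        rates = polymorphism_rates(g, coding_length=800, noncoding_length=800)
        assert rates["noncoding_coding_ratio"] == pytest.approx(1.0)

    def test_rates_match_brute_force(self, paper_sim):
        g = paper_sim.genotypes
        rates = polymorphism_rates(g, coding_length=13827, noncoding_length=30396)
        n_cod = n_non = 0
        for j in range(g.n_sites):
            col = g.calls[:, j]
            col = col[col != MISSING]
            if 0 < col.sum() < 2 * len(col):
                if g.sites[j].region_class == "coding":
                    n_cod += 1
                else:
                    n_non += 1
        assert rates["n_coding_polymorphic"] == n_cod
        assert rates["n_noncoding_polymorphic"] == n_non

    def test_specific_site_counted_once(self):
        groups = ["a", "a", "b", "b"]
        calls = np.array([[0], [2], [0], [0]])  # polymorphic only in group a
        g = matrix_from_calls(calls, groups=groups)
        counts, _ = classify_shared_polymorphisms(g)
        assert counts == {frozenset({"a"}): 1}

    def test_partition_is_exhaustive(self, paper_sim):
        g = paper_sim.genotypes
        counts, site_sets = classify_shared_polymorphisms(g)
        poly_any = sum(1 for s in site_sets if s)
        assert sum(counts.values()) == poly_any

    def test_matches_set_enumeration_oracle(self, paper_sim):
        g = paper_sim.genotypes
        counts, _ = classify_shared_polymorphisms(g)
        groups = sorted(set(g.groups))
        oracle: dict = {}
        for j in range(g.n_sites):
            members = []
            for grp in groups:
                rows = [i for i, x in enumerate(g.groups) if x == grp]
                col = g.calls[rows, j]
                col = col[col != MISSING]
                if len(col) and 0 < col.sum() < 2 * len(col):
                    members.append(grp)
            if members:
                key = frozenset(members)
                oracle[key] = oracle.get(key, 0) + 1
        assert counts == oracle


class TestSpectrum:
    def test_single_occupied_bin(self):
        calls = np.array([[0, 0], [2, 2], [0, 0], [2, 2]])  # both MAF 0.5
        g = matrix_from_calls(calls)
        hist = maf_spectrum(g, overall_prefilter=None)
        assert hist["count"].sum() == 2
        assert hist.loc[hist["bin_high"] == 0.5, "count"].iloc[0] == 2

    def test_counts_conserved(self, paper_sim):
        g = paper_sim.genotypes
        hist = maf_spectrum(g, overall_prefilter=0.05)
        retained = filter_by_maf(g, 0.05)
        n_poly = int(np.sum(np.nan_to_num(site_mafs(retained), nan=0) > 0))
        assert hist["count"].sum() == n_poly

    def test_cultivated_excess_of_rare_alleles(self):
        """The bottlenecked crop group shows an excess of low-frequency
        variants relative to the wild group (aggregated over seeds at a
        matched sample size of 10, so MAF granularity is comparable)."""
        from admixscan.simulate import make_fixture

        agg = {"esculentum": None, "pimpinellifolium": None}
        for seed in range(8):
            g = make_fixture("paper_like", seed=seed).genotypes
            for grp in agg:
                idx = [i for i, x in enumerate(g.groups) if x == grp][:10]
                mask = np.zeros(g.n_accessions, bool)
                mask[idx] = True
                counts = maf_spectrum(g, mask, overall_prefilter=0.05)["count"]
                agg[grp] = counts if agg[grp] is None else agg[grp] + counts
        frac = {g_: c.iloc[0] / c.sum() for g_, c in agg.items()}
        assert frac["esculentum"] > frac["pimpinellifolium"]

    def test_singleton_counter(self):
        calls = np.zeros((6, 3), dtype=int)
        calls[0, 0] = 2  # single carrier accession
        calls[0, 1] = 1  # single copy
        calls[:3, 2] = 2  # three carriers
        g = matrix_from_calls(calls)
        assert singleton_count(g) == 2
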