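"""Overlap rules, Venn partition and chi-square enrichment."""

import numpy as np
import pytest
from scipy import stats

from cleftscan import OverlapRule, classify_against, enrichment_chi2, percent_overlap, venn_partition
from conftest import make_peakset
from _oracles import member_fraction, member_min_bp, random_intervals


class TestOverlapRule:
    def test_validation(self):
        with pytest.raises(ValueError):
            OverlapRule("x", "fraction_of_query", 0.0)
        with pytest.raises(ValueError):
            OverlapRule("x", "min_bp", 0)
        with pytest.raises(ValueError):
            OverlapRule("x", "nope", 1)


class TestClassifyAgainst:
    def test_fraction_threshold_inclusive(self):
        q = make_peakset([("chr1", 0, 100)])
        r = make_peakset([("chr1", 50, 150)])
        assert classify_against(q, r, OverlapRule("r", "fraction_of_query", 0.5)).all()

    def test_union_coverage_not_double_counted(self):
        # two reference pieces cover 30 + 30 bp of a 100 bp query -> 0.6
        q = make_peakset([("chr1", 0, 100)])
        r = make_peakset([("chr1", 0, 30), ("chr1", 40, 70)])
        assert classify_against(q, r, OverlapRule("r", "fraction_of_query", 0.5))[0]
        assert not classify_against(q, r, OverlapRule("r", "fraction_of_query", 0.61))[0]

    def test_min_bp_single_base(self):
        q = make_peakset([("chr1", 0, 100)])
        r = make_peakset([("chr1", 99, 200)])
        assert classify_against(q, r, OverlapRule("r", "min_bp", 1))[0]

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"chr1": 3000, "chr2": 2000}
        qt = sorted(random_intervals(rng, 12, genome, 10, 200))  # PeakSet order
        rt = random_intervals(rng, 15, genome, 10, 300)
        q, r = make_peakset(qt), make_peakset(rt)
        for thr in (0.25, 0.5, 1.0):
            got = classify_against(q, r, OverlapRule("r", "fraction_of_query", thr))
            exp = [member_fraction(t, rt, thr) for t in qt]
            assert got.tolist() == exp
        for bp in (1, 10, 50):
            got = classify_against(q, r, OverlapRule("r", "min_bp", bp))
            exp = [member_min_bp(t, rt, bp) for t in qt]
            assert got.tolist() == exp

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(42)
        genome = {"chr1": 5000}
        q = make_peakset(random_intervals(rng, 30, genome, 10, 200))
        r = make_peakset(random_intervals(rng, 30, genome, 10, 300))
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.8, 1.0):
            cur = classify_against(q, r, OverlapRule("r", "fraction_of_query", thr))
            if prev is not None:
                assert not (cur & ~prev).any()  # raising threshold never adds
            prev = cur

    def test_tiny_fraction_equals_min_bp_one(self):
        rng = np.random.default_rng(43)
        genome = {"chr1": 5000}
        q = make_peakset(random_intervals(rng, 30, genome, 10, 200))
        r = make_peakset(random_intervals(rng, 30, genome, 10, 300))
        frac = classify_against(q, r, OverlapRule("r", "fraction_of_query", 1e-9))
        bp1 = classify_against(q, r, OverlapRule("r", "min_bp", 1))
        assert (frac == bp1).all()


class TestVennPartition:
    def _rules(self):
        return [
            OverlapRule("A", "min_bp", 1),
            OverlapRule("B", "min_bp", 1),
            OverlapRule("C", "fraction_of_query", 0.5),
        ]

    def test_counts_sum_to_total_and_match_enumeration(self):
        # 10 query peaks with hand-constructed memberships
        q = make_peakset([("chr1", i * 1000, i * 1000 + 100) for i in range(10)])
        refs = {
            "A": make_peakset([("chr1", i * 1000, i * 1000 + 100) for i in (0, 1, 2, 3)]),
            "B": make_peakset([("chr1", i * 1000, i * 1000 + 100) for i in (2, 3, 4)]),
            "C": make_peakset([("chr1", i * 1000, i * 1000 + 100) for i in (3, 5)]),
        }
        res = venn_partition(q, self._rules(), refs, named_classes={"spec": "A & B & ~C"})
        assert res.cell_counts["count"].sum() == 10
        assert res.count_in("A") == 4
        assert res.named_class_counts["spec"] == 1  # only peak 2
        assert res.union_count() == 6
        assert res.outside_union_count() == 4  # peaks 6..9

    def test_peak_in_all_and_in_none(self):
        q = make_peakset([("chr1", 0, 100), ("chr1", 5000, 5100)])
        ref = make_peakset([("chr1", 0, 100)])
        res = venn_partition(
            q, [OverlapRule(l, "min_bp", 1) for l in "ABC"],
            {l: ref for l in "ABC"},
        )
        assert res.union_count() == 1
        assert res.outside_union_count() == 1

    def test_missing_reference_errors(self):
        q = make_peakset([("chr1", 0, 100)])
        with pytest.raises(KeyError):
            venn_partition(q, [OverlapRule("A", "min_bp", 1)], {})

    def test_reporting_percentages(self):
        assert percent_overlap(2678, 2845) == 94.1
        assert percent_overlap(1634, 2678, ndigits=0) == 61


class TestEnrichmentChi2:
    def test_reference_covering_genome_gives_p_one(self):
        genome = {"chr1": 10_000}
        q = make_peakset(random_intervals(np.random.default_rng(0), 20, genome, 10, 100))
        ref = make_peakset([("chr1", 0, 10_000)])
        res = enrichment_chi2(q, ref, OverlapRule("r", "min_bp", 1), genome, 100, seed=1)
        assert res.observed_overlapping == res.expected_overlapping == 20
        assert res.chi2_stat == 0 and res.p_value == 1.0

    def test_empty_reference_degenerate(self):
        genome = {"chr1": 10_000}
        q = make_peakset([("chr1", 0, 100)])
        ref = make_peakset([])
        res = enrichment_chi2(q, ref, OverlapRule("r", "min_bp", 1), genome, 100, seed=1)
        assert res.degenerate and res.p_value == 1.0

    def test_strong_enrichment_matches_closed_form(self):
        # reference covers 1% of a 1 Mb genome; all 100 query peaks inside it
        genome = {"chr1": 1_000_000}
        ref = make_peakset([("chr1", 0, 10_000)])
        q = make_peakset([("chr1", i * 100, i * 100 + 50) for i in range(100)])
        res = enrichment_chi2(q, ref, OverlapRule("r", "min_bp", 1), genome, 500, seed=2)
        assert res.observed_overlapping == 100
        e = res.expected_overlapping
        expected_chi2 = (100 - e) ** 2 / e + (100 - e)
        assert res.chi2_stat == pytest.approx(expected_chi2)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(expected_chi2, 1)))
        assert res.p_value < 1e-10

    def test_requires_minimum_permutations(self):
        genome = {"chr1": 1000}
        q = make_peakset([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            enrichment_chi2(q, q, OverlapRule("r", "min_bp", 1), genome, n_perm=10)


def _null_pvalues(n_sims, seed0, n_peaks=300, n_perm=100):
    """Enrichment p-values when the query itself is drawn from the null."""
    genome = {"chr1": 1_000_000}
    rng = np.random.default_rng(12345)
    ref = make_peakset(random_intervals(rng, 600, genome, 500, 1500))
    rule = OverlapRule("r", "min_bp", 1)
    pvals = []
    for i in range(n_sims):
        r = np.random.default_rng(seed0 + i)
        starts = r.integers(0, 1_000_000 - 300, size=n_peaks)
        q = make_peakset([("chr1", int(s), int(s) + 300) for s in starts])
        pvals.append(
            enrichment_chi2(q, ref, rule, genome, n_perm=n_perm, seed=seed0 + i).p_value
        )
    return np.array(pvals)


class TestEnrichmentCalibration:
    @pytest.fixture(scope="class")
    @staticmethod
    def null_pvals():
        return _null_pvalues(1000, seed0=50_000)

    def test_null_pvalues_uniform(self, null_pvals):
        ks = stats.kstest(null_pvals[:500], "uniform")
        assert ks.pvalue > 0.01

    def test_type_one_error_near_nominal(self, null_pvals):
        rate = float((null_pvals < 0.05).mean())
        assert 0.03 <= rate <= 0.07
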