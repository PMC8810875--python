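"""Interval model, BED I/O, filtering and the replicate-intersection rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftscan import (
    GenomicInterval,
    Peak,
    PeakSet,
    derive_hc_peaks,
    filter_peaks,
    overlap_bp,
    read_bed,
    write_bed,
)
from conftest import make_peakset
from _oracles import base_set, hc_base_set, random_intervals


class TestGenomicInterval:
    def test_rejects_degenerate_spans(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)

    def test_length(self):
        assert GenomicInterval("chr1", 100, 200).length == 100


class TestOverlapBp:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (("chr1", 0, 100), ("chr1", 50, 150), 50),
            (("chr1", 0, 100), ("chr1", 100, 200), 0),  # half-open abutment
            (("chr1", 0, 100), ("chr2", 0, 100), 0),
            (("chr1", 10, 20), ("chr1", 0, 100), 10),  # containment
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 100),
        s2=st.integers(0, 500), l2=st.integers(1, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_base_count(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        expected = len(
            set(range(s1, s1 + l1)) & set(range(s2, s2 + l2))
        )
        assert overlap_bp(a, b) == expected


class TestBedIO:
    def test_bed3_parse(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        ps = read_bed(p, dialect="bed3")
        assert len(ps) == 1
        assert (ps[0].interval.chrom, ps[0].interval.start, ps[0].interval.end) == (
            "chr1", 100, 200,
        )

    def test_narrowpeak_q_column_is_neglog10(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t0\t500\tpk1\t100\t.\t12.5\t-1\t2.0\t250\n")
        pk = read_bed(p, dialect="narrowPeak")[0]
        assert pk.fdr_q == pytest.approx(0.01)
        assert pk.fold_enrichment == 12.5
        assert pk.summit_offset == 250

    def test_empty_file_yields_empty_set(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p, dialect="bed3")) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\toops\t200\n")
        with pytest.raises(ValueError, match=":2"):
            read_bed(p, dialect="bed3")

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(ValueError, match="end <= start"):
            read_bed(p, dialect="bed3")

    def test_round_trip_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        ps = make_peakset(random_intervals(rng, 30, {"chr1": 5000, "chr2": 4000}))
        out = tmp_path / "rt.bed"
        write_bed(ps, out, dialect="bed6")
        back = read_bed(out, dialect="bed6")
        assert [
            (p.interval.chrom, p.interval.start, p.interval.end, p.interval.name)
            for p in back
        ] == [
            (p.interval.chrom, p.interval.start, p.interval.end, p.interval.name)
            for p in ps
        ]

    def test_peaks_must_fit_chromosome(self):
        with pytest.raises(ValueError, match="exceeds"):
            make_peakset([("chr1", 0, 2000)], genome={"chr1": 1000})


class TestFilterPeaks:
    def _ps(self, specs):
        peaks = [
            Peak(GenomicInterval(c, s, e, name=f"p{i}"), fold_enrichment=fe, fdr_q=q)
            for i, (c, s, e, fe, q) in enumerate(specs)
        ]
        return PeakSet(peaks)

    def test_fe_bounds_inclusive_fdr_strict(self):
        ps = self._ps(
            [
                ("chr1", 0, 100, 4.9, 0.01),   # FE below lower bound
                ("chr1", 200, 300, 5.0, 0.01),  # FE at lower bound: kept
                ("chr1", 400, 500, 50.0, 0.049),  # boundary FE, q < 0.05: kept
                ("chr1", 600, 700, 50.1, 0.01),  # FE above upper bound
                ("chr1", 800, 900, 10.0, 0.05),  # q at bound: removed (strict)
            ]
        )
        kept = filter_peaks(ps, 5, 50, 0.05)
        assert [p.interval.start for p in kept] == [200, 400]

    def test_blacklist_single_bp_overlap_removes(self):
        ps = self._ps([("chr1", 0, 100, 10, 0.01), ("chr1", 200, 300, 10, 0.01)])
        blacklist = make_peakset([("chr1", 99, 150)])
        kept = filter_peaks(ps, 5, 50, 0.05, blacklist=blacklist)
        assert [p.interval.start for p in kept] == [200]

    def test_irregular_chromosomes_removed(self):
        ps = self._ps([("chr1", 0, 100, 10, 0.01), ("chrUn_gl000220", 0, 100, 10, 0.01)])
        kept = filter_peaks(ps, 5, 50, 0.05)
        assert len(kept) == 1 and kept[0].interval.chrom == "chr1"

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_peaks(self._ps([]), fe_min=10, fe_max=5)


class TestDeriveHcPeaks:
    def test_simple_intersection(self):
        hc = derive_hc_peaks(make_peakset([("chr1", 0, 100)]),
                             make_peakset([("chr1", 50, 150)]))
        assert [(p.interval.start, p.interval.end) for p in hc] == [(50, 100)]

    def test_unsupported_peak_dropped(self):
        hc = derive_hc_peaks(make_peakset([("chr1", 0, 100)]),
                             make_peakset([("chr1", 200, 300)]))
        assert len(hc) == 0

    def test_one_anchor_two_partners_gives_two_regions(self):
        hc = derive_hc_peaks(
            make_peakset([("chr1", 0, 300)]),
            make_peakset([("chr1", 0, 100), ("chr1", 200, 300)]),
        )
        assert [(p.interval.start, p.interval.end) for p in hc] == [(0, 100), (200, 300)]

    def test_provenance_names_parents(self):
        hc = derive_hc_peaks(
            make_peakset([("chr1", 0, 100)], names=["a1"]),
            make_peakset([("chr1", 50, 150)], names=["b1"]),
        )
        assert hc[0].interval.name == "a1|b1"

    def test_abutting_pieces_merged(self):
        # two rep1 peaks abut; rep2 spans both -> single merged hc region
        hc = derive_hc_peaks(
            make_peakset([("chr1", 0, 100), ("chr1", 100, 200)]),
            make_peakset([("chr1", 0, 200)]),
        )
        assert [(p.interval.start, p.interval.end) for p in hc] == [(0, 200)]

    def test_hc_contained_in_anchor_and_shorter_than_parents(self):
        rng = np.random.default_rng(1)
        genome = {"chr1": 3000}
        rep1 = make_peakset(random_intervals(rng, 12, genome, 20, 300))
        rep2 = make_peakset(random_intervals(rng, 12, genome, 20, 300))
        hc = derive_hc_peaks(rep1, rep2)
        anchors = [(p.interval.start, p.interval.end) for p in rep1]
        for p in hc:
            # abutting merges can span two anchors; every hc base lies in rep1
            assert any(
                s <= b < e for b in range(p.interval.start, p.interval.end)
                for s, e in anchors
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_bp_agreement_with_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genome = {"chr1": 2000, "chr2": 1500}
        t1 = random_intervals(rng, 10, genome, 10, 400)
        t2 = random_intervals(rng, 10, genome, 10, 400)
        hc = derive_hc_peaks(make_peakset(t1), make_peakset(t2))
        got = base_set(
            [(p.interval.chrom, p.interval.start, p.interval.end) for p in hc]
        )
        assert got == hc_base_set(t1, t2)

    @pytest.mark.parametrize("seed", range(10))
    def test_direction_symmetry_at_bp_level(self, seed):
        rng = np.random.default_rng(100 + seed)
        genome = {"chr1": 2000}
        t1 = random_intervals(rng, 8, genome, 10, 300)
        t2 = random_intervals(rng, 8, genome, 10, 300)
        ab = derive_hc_peaks(make_peakset(t1), make_peakset(t2))
        ba = derive_hc_peaks(make_peakset(t2), make_peakset(t1))
        bases = lambda ps: base_set(
            [(p.interval.chrom, p.interval.start, p.interval.end) for p in ps]
        )
        assert bases(ab) == bases(ba)
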