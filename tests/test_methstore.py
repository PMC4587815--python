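"""Methylome store: calling statistics, import/query, coverage gaps."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episuite.fixtures import synth_alignments
from episuite.intervals import Interval
from episuite.methstore import (
    NO_CALL_SENTINEL,
    MethylomeStore,
    adjust_pvalues_bh,
    binomial_mc_pvalue,
    derive_context,
    find_uncovered_regions,
    import_methylation_table,
    parse_mlml,
)

from conftest import write_table


def brute_binom_sf(c, t, p0):
    n = c + t
    return sum(comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(c, n + 1))


class TestBinomialCall:
    @pytest.mark.parametrize(
        "c,t,p0,expected",
        [
            (0, 10, 0.01, 1.0),
            (2, 0, 0.01, 1.0e-4),
            (5, 5, 0.05, 6.368983144531251e-05),
        ],
    )
    def test_known_values(self, c, t, p0, expected):
        assert binomial_mc_pvalue(c, t, p0) == pytest.approx(expected, rel=1e-10)

    def test_matches_brute_force_summation(self):
        for p0 in (0.001, 0.011, 0.05):
            for n in (1, 2, 5, 17, 50):
                for c in range(n + 1):
                    assert binomial_mc_pvalue(c, n - c, p0) == pytest.approx(
                        brute_binom_sf(c, n - c, p0), abs=1e-12
                    )

    def test_monotone_in_c_at_fixed_depth(self):
        for n in (1, 5, 30):
            ps = [binomial_mc_pvalue(c, n - c, 0.011) for c in range(n + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("c,t,p0", [(0, 0, 0.5), (1, 1, 0.0), (1, 1, 1.0), (-1, 2, 0.5)])
    def test_rejects_bad_inputs(self, c, t, p0):
        with pytest.raises(ValueError):
            binomial_mc_pvalue(c, t, p0)


class TestBHCorrection:
    def test_identity_and_ties(self):
        assert adjust_pvalues_bh([0.3]) == pytest.approx([0.3])
        assert adjust_pvalues_bh([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])
        assert adjust_pvalues_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert adjust_pvalues_bh([]).size == 0

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_sort_based_oracle(self, pvals):
        def oracle(p):
            m = len(p)
            order = sorted(range(m), key=lambda i: p[i])
            out = [0.0] * m
            best = math.inf
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                best = min(best, p[i] * m / rank)
                out[i] = min(best, 1.0)
            return out

        assert adjust_pvalues_bh(pvals) == pytest.approx(oracle(pvals), abs=1e-12)


class TestContextDerivation:
    @pytest.mark.parametrize(
        "seq,idx,strand,expected",
        [
            ("ACGT", 1, "+", "CG"),
            ("ACAGT", 1, "+", "CHG"),
            ("ACAAT", 1, "+", "CHH"),
            ("ACGT", 2, "-", "CG"),
            ("CAGTT", 2, "-", "CHG"),
            ("TAGTT", 2, "-", "CHH"),
            ("AAGT", 0, "+", None),  # not a C
        ],
    )
    def test_contexts(self, seq, idx, strand, expected):
        assert derive_context(seq, idx, strand) == expected


class TestImportAndQuery:
    ROWS = [
        ("chr1", 100, "+", "CG", 5, 5),
        ("chr1", 50, "+", "CG", 0, 8),   # no C support: dropped
        ("chr1", 200, "+", "CHH", 2, 10),
        ("chr2", 10, "-", "CG", 12, 0),
    ]

    def test_inclusion_rule_and_sorting(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", self.ROWS)
        store = import_methylation_table(table, "s1", 0.99, 0.001,
                                         str(tmp_path / "s1.gz"))
        recs = list(store.fetch_all())
        assert len(recs) == 3
        assert [(r.chrom, r.pos) for r in recs] == [("chr1", 100), ("chr1", 200), ("chr2", 10)]
        assert store.n_records == 3

    def test_pvalues_recomputable_per_row(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", self.ROWS)
        store = import_methylation_table(table, "s1", 0.99, 0.001,
                                         str(tmp_path / "s1.gz"))
        p0 = (1 - 0.99) + 0.001
        recs = list(store.fetch_all())
        for r in recs:
            assert r.pvalue == pytest.approx(
                binomial_mc_pvalue(r.c_reads, r.t_reads, p0), rel=1e-6
            )
        qs = adjust_pvalues_bh([r.pvalue for r in recs])
        for r, q in zip(recs, qs):
            assert r.qvalue == pytest.approx(q, rel=1e-6)
            assert r.qvalue >= r.pvalue - 1e-12
            assert r.qvalue <= 1.0

    def test_reimport_is_byte_identical(self, tmp_path):
        import gzip

        table = write_table(tmp_path / "t.tsv", self.ROWS)
        a = import_methylation_table(table, "s1", 0.99, 0.001, str(tmp_path / "a.gz"))
        b = import_methylation_table(table, "s1", 0.99, 0.001, str(tmp_path / "b.gz"))
        assert gzip.open(a.path).read() == gzip.open(b.path).read()

    def test_roundtrip_reproduces_retained_rows(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", self.ROWS)
        store = import_methylation_table(table, "s1", 0.99, 0.001,
                                         str(tmp_path / "s1.gz"))
        got = {
            (r.chrom, r.pos, r.strand, r.context, r.c_reads, r.t_reads)
            for chrom in store.chromosomes()
            for r in store.query(chrom, 0, 10**9, min_depth=1, max_q=1.0)
        }
        expected = {row for row in self.ROWS if row[4] >= 1}
        assert got == expected

    def test_query_filters(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", self.ROWS)
        store = import_methylation_table(table, "s1", 0.99, 0.001,
                                         str(tmp_path / "s1.gz"))
        assert store.query("chr1", 100, 100) == []
        assert store.query("chrMissing", 0, 1000) == []
        deep = store.query("chr1", 0, 10**6, min_depth=11)
        assert [r.pos for r in deep] == [200]
        cg_only = store.query("chr1", 0, 10**6, context_filter=["CG"])
        assert [r.pos for r in cg_only] == [100]

    def test_malformed_row_reports_line_number(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", [("chr1", 100, "+", "CG", 5, 5),
                                                 ("chr1", "oops", "+", "CG", 1, 1)])
        with pytest.raises(ValueError, match="line 2"):
            import_methylation_table(table, "s1", 0.99, 0.001, str(tmp_path / "x.gz"))

    def test_impossible_null_probability_rejected(self, tmp_path):
        table = write_table(tmp_path / "t.tsv", self.ROWS)
        with pytest.raises(ValueError, match="p0"):
            import_methylation_table(table, "s1", 0.0, 0.1, str(tmp_path / "x.gz"))

    def test_context_derived_from_genome(self, tmp_path, small_genome):
        import pyfaidx

        fa = pyfaidx.Fasta(small_genome)
        seq = str(fa["chr1"][:]).upper()
        cg_idx = seq.index("CG")
        table = write_table(tmp_path / "t.tsv",
                            [("chr1", cg_idx + 1, "+", ".", 3, 1)])
        store = import_methylation_table(table, "s1", 0.99, 0.001,
                                         str(tmp_path / "s1.gz"), genome=small_genome)
        assert next(store.fetch_all()).context == "CG"


class TestMlml:
    ROWS = [
        ("chr1", 100, "+", "CG", 0.5, 0.2, 10),
        ("chr1", 200, "+", "CG", 0.9, 0.0, 10),  # zero hmC: dropped
        ("chr1", 300, "+", "CG", 0.1, 0.5, 20),
    ]

    def test_parse_levels_and_inclusion(self, tmp_path):
        table = write_table(tmp_path / "m.tsv", self.ROWS)
        store = parse_mlml(table, "hmc", str(tmp_path / "h.gz"))
        recs = list(store.fetch_all())
        assert [(r.pos, r.level) for r in recs] == [(100, 0.2), (300, 0.5)]
        assert all(r.qvalue == NO_CALL_SENTINEL for r in recs)

    def test_sentinel_records_need_flag(self, tmp_path):
        table = write_table(tmp_path / "m.tsv", self.ROWS)
        store = parse_mlml(table, "hmc", str(tmp_path / "h.gz"))
        assert store.query("chr1", 0, 1000, max_q=0.05) == []
        assert len(store.query("chr1", 0, 1000, max_q=0.05, include_nocall=True)) == 2

    def test_empty_file(self, tmp_path):
        table = write_table(tmp_path / "m.tsv", [])
        store = parse_mlml(table, "hmc", str(tmp_path / "h.gz"))
        assert list(store.fetch_all()) == []


class TestUncoveredRegions:
    def test_no_reads_whole_chromosome(self, tmp_path):
        bam = synth_alignments({"chrZ": 1000}, str(tmp_path / "e.bam"),
                               background_rate=0.0, seed=0)
        gaps = find_uncovered_regions(bam, min_gap=1)
        assert [(g.chrom, g.start, g.end) for g in gaps] == [("chrZ", 0, 1000)]

    def test_single_read_splits_chromosome(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chrZ", "LN": 1000}]}
        path = str(tmp_path / "hand.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as out:
            a = pysam.AlignedSegment(out.header)
            a.query_name = "r1"
            a.reference_id = 0
            a.reference_start = 100
            a.cigarstring = "50M"
            a.query_sequence = "A" * 50
            a.mapping_quality = 60
            out.write(a)
        pysam.index(path)
        gaps = find_uncovered_regions(path, min_gap=50)
        assert [(g.start, g.end) for g in gaps] == [(0, 100), (150, 1000)]

    def test_full_coverage_yields_nothing(self, tmp_path):
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chrZ", "LN": 200}]}
        path = str(tmp_path / "full.bam")
        with pysam.AlignmentFile(path, "wb", header=header) as out:
            for i, start in enumerate(range(0, 200, 50)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"r{i}"
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.query_sequence = "A" * 50
                a.mapping_quality = 60
                out.write(a)
        pysam.index(path)
        assert len(find_uncovered_regions(path, min_gap=1)) == 0
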