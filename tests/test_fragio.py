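"""Fragment reconstruction, deduplication, yield arithmetic and table I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbdqc.fragio import (
    AlignedPair,
    FilterTally,
    MappedFragment,
    ReferenceGenome,
    deduplicate_fragments,
    read_alignment_pairs,
    read_fragments_bed,
    read_methylation_table,
    read_reference,
    reconstruct_fragments,
    write_fasta,
    write_fragments_bed,
    write_pairs_bedpe,
    yield_summary,
)


def _pair(pos1, pos2, len1=45, len2=45, chrom="chr1", **kw):
    defaults = dict(unique1=True, unique2=True, proper_orientation=True, same_chrom=True)
    defaults.update(kw)
    return AlignedPair(chrom, pos1, pos2, len1, len2, **defaults)


class TestReadAlignmentPairs:
    def test_bedpe_line(self, tmp_path):
        p = tmp_path / "one.bedpe"
        p.write_text("chr1\t100\t145\tchr1\t300\t345\tfrag1\t60\t+\t-\n")
        (pair,) = read_alignment_pairs(p, dialect="bedpe")
        assert (pair.chrom, pair.pos1, pair.pos2) == ("chr1", 100, 300)
        assert (pair.len1, pair.len2) == (45, 45)
        assert pair.unique1 and pair.unique2 and pair.proper_orientation

    def test_sam_mapq_sets_unique_flags(self, ten_pair_sam):
        pairs = read_alignment_pairs(ten_pair_sam, dialect="sam")
        assert len(pairs) == 10
        by_order = {i: p for i, p in enumerate(pairs)}
        assert by_order[0].unique1 and by_order[0].unique2  # p01, MAPQ 60
        assert not by_order[5].unique2  # p06, mate MAPQ 5
        assert not (by_order[6].unique1 or by_order[6].unique2)  # p07, MAPQ 0
        assert not by_order[7].unique2  # p08, mate unmapped

    def test_cross_chromosome_pair_not_proper(self, ten_pair_sam):
        pairs = read_alignment_pairs(ten_pair_sam, dialect="sam")
        p09 = pairs[8]
        assert not p09.same_chrom and not p09.proper_orientation

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_alignment_pairs(tmp_path / "x", dialect="bam")

    def test_malformed_bedpe_names_line(self, tmp_path):
        p = tmp_path / "bad.bedpe"
        p.write_text("chr1\t100\t145\tchr1\t300\t345\n" "chr1\tnope\t1\tchr1\t2\t3\n")
        with pytest.raises(ValueError, match="line 2"):
            read_alignment_pairs(p, dialect="bedpe")


class TestReconstructFragments:
    def test_span_within_limit(self):
        frags = reconstruct_fragments([_pair(100, 300)], max_span=400)
        assert frags == [MappedFragment("chr1", 100, 345, 1)]

    def test_over_span_dropped(self):
        assert reconstruct_fragments([_pair(100, 700)], max_span=400) == []

    def test_mate_order_irrelevant(self):
        a = reconstruct_fragments([_pair(300, 100)])
        b = reconstruct_fragments([_pair(100, 300)])
        assert a == b

    def test_start_distance_metric(self):
        # outer span 245 > 200 but start distance 200 <= 200
        pair = _pair(100, 300)
        assert reconstruct_fragments([pair], max_span=200) == []
        assert len(reconstruct_fragments([pair], max_span=200, span_metric="start_distance")) == 1

    def test_ten_pair_fixture_filter_outcomes(self, ten_pair_sam):
        """3 non-unique + 1 cross-chromosome rejected -> 6 fragments."""
        pairs = read_alignment_pairs(ten_pair_sam, dialect="sam")
        tally = FilterTally()
        frags = reconstruct_fragments(pairs, tally=tally)
        assert len(frags) == 6
        assert tally.non_unique == 3
        assert tally.cross_chromosome == 1
        assert tally.improper_orientation == 0 and tally.over_span == 0
        assert sorted((f.chrom, f.start, f.end) for f in frags) == [
            ("chr1", 10, 255),
            ("chr1", 60, 305),
            ("chr1", 100, 445),
            ("chr1", 100, 445),
            ("chr1", 500, 845),
            ("chr2", 50, 295),
        ]

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 1000),
                st.integers(0, 1000),
                st.booleans(),
                st.booleans(),
                st.booleans(),
                st.booleans(),
            ),
            max_size=60,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_pair_count_conservation(self, raw):
        """Every input pair is either emitted or rejected by exactly one filter."""
        pairs = [
            AlignedPair(
                "chr1", p1, p2, 45, 45,
                unique1=u1, unique2=u2,
                proper_orientation=prop and same, same_chrom=same,
            )
            for p1, p2, u1, u2, prop, same in raw
        ]
        tally = FilterTally()
        frags = reconstruct_fragments(pairs, tally=tally)
        assert tally.kept == len(frags)
        assert tally.total_in() == len(pairs)


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        f = MappedFragment("chr1", 100, 345)
        (out,) = deduplicate_fragments([f, f])
        assert out.multiplicity == 2

    def test_all_distinct_identity(self):
        frags = [MappedFragment("chr1", i, i + 100) for i in range(10)]
        out = deduplicate_fragments(frags)
        assert out == frags

    def test_random_draws_match_set_of_tuples(self):
        rng = np.random.default_rng(7)
        distinct = [(int(s), int(s) + int(l)) for s, l in
                    zip(rng.integers(0, 5000, 200), rng.integers(50, 400, 200))]
        draws = [distinct[i] for i in rng.integers(0, 200, 1000)]
        frags = [MappedFragment("chr1", s, e) for s, e in draws]
        out = deduplicate_fragments(frags)
        assert len(out) == len({("chr1", s, e) for s, e in draws})

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 20)), max_size=200))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_multiplicity_conservation(self, raw):
        frags = [MappedFragment("chr1", s, s + l) for s, l in raw]
        out = deduplicate_fragments(frags)
        assert sum(f.multiplicity for f in out) == len(frags)


class TestYieldSummary:
    @pytest.mark.parametrize(
        "counts, pct_unique, pct_nondup",
        [
            ((11_531_844, 6_632_940, 3_916_243), 57.5, 59.0),
            ((155_564, 81_179, 10_054), 52.2, 12.4),
            ((100, 100, 100), 100.0, 100.0),
        ],
    )
    def test_percentage_convention(self, counts, pct_unique, pct_nondup):
        s = yield_summary(*counts)
        assert s.pct_unique_of_sequenced == pct_unique
        assert s.pct_nondup_of_unique == pct_nondup

    def test_zero_denominator_missing(self):
        s = yield_summary(0, 0, 0)
        assert s.pct_unique_of_sequenced is None and s.pct_nondup_of_unique is None

    def test_disordered_counts_rejected(self):
        with pytest.raises(ValueError):
            yield_summary(10, 20, 5)


class TestReference:
    def test_single_record(self, tmp_path):
        p = tmp_path / "c.fa"
        p.write_text(">c\nACGT\n")
        g = read_reference(p)
        assert g.length("c") == 4 and g.fetch("c", 0, 4) == "ACGT"

    def test_soft_mask_preserved(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">m\nacgt\n")
        assert read_reference(p).fetch("m", 0, 4) == "acgt"

    def test_out_of_bounds(self, tmp_path):
        p = tmp_path / "c.fa"
        p.write_text(">c\nACGT\n")
        with pytest.raises(IndexError):
            read_reference(p).fetch("c", 2, 6)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ValueError):
            read_reference(p)

    def test_fasta_round_trip(self, tmp_path, toy_genome):
        p = tmp_path / "rt.fa"
        write_fasta(toy_genome, p)
        back = read_reference(p)
        assert back["chr1"] == toy_genome["chr1"] and back["chr2"] == toy_genome["chr2"]


class TestMethylationTable:
    def test_strand_merge_sums_counts(self, tmp_path):
        p = tmp_path / "two.tsv"
        p.write_text(
            "chrom\tpos\tstrand\tmeth_count\ttotal_count\n"
            "chr1\t10\t+\t8\t10\nchr1\t11\t-\t2\t10\n"
        )
        t = read_methylation_table(p, "rrbs")
        assert len(t) == 1
        row = t.df.iloc[0]
        assert (row["pos"], row["degree"], row["coverage"]) == (10, 0.5, 20)

    def test_six_rows_merge_to_three(self, rrbs_six_rows):
        t = read_methylation_table(rrbs_six_rows, "rrbs")
        assert len(t) == 3
        got = {(r.chrom, r.pos): (r.degree, r.coverage) for r in t.df.itertuples()}
        assert got[("chr1", 10)] == (0.5, 20)
        assert got[("chr1", 50)] == (0.45, 20)
        assert got[("chr2", 7)] == (0.1, 10)

    def test_merge_halves_fully_paired_fixture(self, rrbs_six_rows):
        kept = read_methylation_table(rrbs_six_rows, "rrbs", strand_mode="keep")
        merged = read_methylation_table(rrbs_six_rows, "rrbs", strand_mode="merge")
        assert len(merged) * 2 == len(kept)

    def test_array_beta(self, tmp_path):
        p = tmp_path / "arr.tsv"
        p.write_text("chrom\tpos\tbeta\nchr1\t10\t0.87\n")
        t = read_methylation_table(p, "array")
        assert t.df.iloc[0]["degree"] == 0.87
        assert t.df.iloc[0]["coverage"] > 10**12  # unlimited sentinel

    def test_beta_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrom\tpos\tbeta\nchr1\t10\t1.2\n")
        with pytest.raises(ValueError):
            read_methylation_table(p, "array")


class TestBedRoundTrip:
    def test_intervals_and_multiplicities_survive(self, tmp_path):
        rng = np.random.default_rng(11)
        frags = [
            MappedFragment("chr1", int(s), int(s) + int(l), multiplicity=int(m))
            for s, l, m in zip(
                rng.integers(0, 900, 50), rng.integers(50, 400, 50), rng.integers(1, 9, 50)
            )
        ]
        p = tmp_path / "f.bed"
        write_fragments_bed(frags, p)
        assert read_fragments_bed(p) == frags

    def test_bedpe_emission_reconstructs_fragment(self, tmp_path):
        frags = [MappedFragment("chr1", 100, 345)]
        p = tmp_path / "f.bedpe"
        write_pairs_bedpe(frags, p)
        pairs = read_alignment_pairs(p, dialect="bedpe")
        assert reconstruct_fragments(pairs) == frags
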