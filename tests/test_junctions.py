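"""Transread detection, counting, and known/novel classification."""

import random

import pytest

from spliceff.alignments import SplicedAlignment
from spliceff.annotation import IntronRecord
from spliceff.junctions import (
    AMBIGUOUS,
    GapDiagnostics,
    KNOWN,
    NOVEL,
    NOVEL_ACCEPTOR,
    NOVEL_DONOR,
    NOVEL_PAIR,
    JunctionRecord,
    annotate_junctions,
    extract_junctions,
    junction_count_table,
    write_junction_counts,
)


def _aln(cigar_blocks, gaps, chrom="chrI", strand="+", read_id="r"):
    return SplicedAlignment(
        read_id=read_id,
        chrom=chrom,
        blocks=cigar_blocks,
        gaps=gaps,
        mapq=60,
        read_strand=strand,
    )


def _spliced(start, left, intron, right, chrom="chrI", read_id="r"):
    gap_start = start + left
    gap_end = gap_start + intron
    return _aln(
        [(start, gap_start), (gap_end, gap_end + right)],
        [(gap_start, gap_end)],
        chrom=chrom,
        read_id=read_id,
    )


class TestExtractJunctions:
    def test_single_transread(self):
        (j,) = extract_junctions([_spliced(0, 20, 60, 80)], min_anchor=8)
        assert (j.chrom, j.start, j.end, j.transread_count) == ("chrI", 20, 80, 1)
        assert (j.max_left_anchor, j.max_right_anchor) == (20, 80)

    @pytest.mark.parametrize(
        "intron_len,expected", [(19, 0), (20, 1), (10000, 1), (10001, 0)]
    )
    def test_intron_length_bounds_inclusive(self, intron_len, expected):
        out = extract_junctions([_spliced(0, 30, intron_len, 30)])
        assert len(out) == expected

    @pytest.mark.parametrize(
        "left,right,expected", [(5, 95, 0), (8, 92, 1), (95, 5, 0), (8, 8, 1)]
    )
    def test_anchor_rule(self, left, right, expected):
        out = extract_junctions([_spliced(0, left, 60, right)], min_anchor=8)
        assert len(out) == expected

    def test_two_reads_sharing_a_gap_count_twice(self):
        alns = [_spliced(0, 20, 60, 80), _spliced(10, 10, 60, 90)]
        (j,) = extract_junctions(alns)
        assert j.transread_count == 2

    def test_multi_gap_read_supports_each_qualifying_gap(self):
        aln = _aln(
            [(0, 20), (80, 100), (200, 220)],
            [(20, 80), (100, 200)],
        )
        out = extract_junctions([aln])
        assert [(j.start, j.end, j.transread_count) for j in out] == [
            (20, 80, 1),
            (100, 200, 1),
        ]

    def test_evidence_is_conserved(self):
        """Sum of transread counts equals the number of qualifying gaps."""
        rng = random.Random(0)
        alns = []
        for i in range(100):
            start = rng.randrange(0, 500)
            alns.append(
                _spliced(start, rng.randrange(1, 40), rng.randrange(10, 120),
                         rng.randrange(1, 40), read_id=f"r{i}")
            )
        diag = GapDiagnostics()
        out = extract_junctions(alns, diagnostics=diag)
        assert sum(j.transread_count for j in out) == diag.qualifying
        total_gaps = sum(len(a.gaps) for a in alns)
        assert (
            diag.qualifying + diag.too_short + diag.too_long + diag.short_anchor
            == total_gaps
        )

    def test_order_permutation_invariance(self):
        rng = random.Random(1)
        alns = [
            _spliced(rng.randrange(0, 300), 20, 60, 20, read_id=f"r{i}")
            for i in range(50)
        ]
        shuffled = alns[:]
        rng.shuffle(shuffled)
        key = lambda recs: [(j.key, j.transread_count) for j in recs]
        assert key(extract_junctions(alns)) == key(extract_junctions(shuffled))


class TestAnnotateJunctions:
    INTRONS = [
        IntronRecord("chrI", 100, 200, "+", "g1"),
        IntronRecord("chrI", 300, 380, "-", "g2"),
        IntronRecord("chrI", 500, 600, "+", "g3"),
    ]

    def _classify(self, start, end):
        (j,) = annotate_junctions(
            [JunctionRecord("chrI", start, end, transread_count=1)], self.INTRONS
        )
        return j

    @pytest.mark.parametrize(
        "start,end,expected_class,expected_strand",
        [
            (100, 200, KNOWN, "+"),
            (100, 250, NOVEL_ACCEPTOR, "+"),  # donor (low, + strand) matches
            (120, 200, NOVEL_DONOR, "+"),  # acceptor matches
            (300, 350, NOVEL_DONOR, "-"),  # low boundary is the acceptor on '-'
            (250, 380, NOVEL_ACCEPTOR, "-"),  # high boundary is the donor on '-'
            (100, 600, NOVEL_PAIR, "+"),  # boundaries of different introns
            (400, 450, NOVEL, "unknown"),
        ],
    )
    def test_classification(self, start, end, expected_class, expected_strand):
        j = self._classify(start, end)
        assert j.annotation_class == expected_class
        assert j.strand == expected_strand

    def test_known_junction_inherits_gene(self):
        assert self._classify(100, 200).gene_id == "g1"

    def test_both_strand_exact_match_is_ambiguous(self, caplog):
        introns = [
            IntronRecord("chrI", 100, 200, "+", "g1"),
            IntronRecord("chrI", 100, 200, "-", "g2"),
        ]
        with caplog.at_level("WARNING"):
            (j,) = annotate_junctions(
                [JunctionRecord("chrI", 100, 200, transread_count=3)], introns
            )
        assert j.annotation_class == AMBIGUOUS
        assert "both strands" in caplog.text


class TestJunctionTables:
    def _records(self, counts):
        recs = [
            JunctionRecord("chrI", 100, 200, transread_count=c) for c in [counts]
        ]
        return annotate_junctions(recs, TestAnnotateJunctions.INTRONS)

    def test_counts_per_sample_columns(self, tmp_path):
        per_sample = {"s1": self._records(3), "s2": self._records(7)}
        known, novel = write_junction_counts(
            per_sample, tmp_path / "known.csv", tmp_path / "novel.csv"
        )
        assert len(known) == 1 and len(novel) == 0
        row = known.iloc[0]
        assert (row["s1"], row["s2"]) == (3, 7)
        assert (tmp_path / "known.csv").read_text().splitlines()[0] == (
            "chrom,start,end,strand,annotation_class,gene_id,s1,s2"
        )

    def test_junction_absent_in_one_sample_fills_zero(self):
        novel = annotate_junctions(
            [JunctionRecord("chrI", 400, 450, transread_count=2)],
            TestAnnotateJunctions.INTRONS,
        )
        table = junction_count_table({"s1": self._records(5), "s2": novel})
        assert set(table["annotation_class"]) == {KNOWN, NOVEL}
        known_row = table[table["annotation_class"] == KNOWN].iloc[0]
        assert (known_row["s1"], known_row["s2"]) == (5, 0)

    def test_no_known_junctions_yields_header_only_csv(self, tmp_path):
        per_sample = {
            "s1": annotate_junctions(
                [JunctionRecord("chrI", 400, 450, transread_count=1)],
                TestAnnotateJunctions.INTRONS,
            )
        }
        known, novel = write_junction_counts(
            per_sample, tmp_path / "known.csv", tmp_path / "novel.csv"
        )
        assert len(known) == 0 and len(novel) == 1
        assert len((tmp_path / "known.csv").read_text().splitlines()) == 1
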