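"""Span-span and exon-exon overlap scoring against per-base oracles."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudolap.models import GenomicInterval, Orientation, Strand
from pseudolap.scoring import (
    exon_exon_score,
    overlap_length,
    relative_orientation,
    span_span_score,
)

from conftest import gene_models, make_gene
from oracles import brute_exon_exon, brute_overlap_length, brute_span_span


def iv(start: int, end: int, chrom: str = "chr1", strand: str = "+") -> GenomicInterval:
    return GenomicInterval(chrom, start, end, Strand(strand))


class TestOverlapLength:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((100, 200), (150, 250), 51),
            ((1, 100), (1, 100), 100),
            ((1, 100), (101, 200), 0),  # abutting closed intervals share no base
            ((1, 100), (100, 200), 1),
            ((50, 60), (1, 100), 11),
        ],
    )
    def test_shared_base_count(self, a, b, expected):
        assert overlap_length(iv(*a), iv(*b)) == expected
        assert overlap_length(iv(*b), iv(*a)) == expected  # symmetry
        assert brute_overlap_length(iv(*a), iv(*b)) == expected

    def test_different_chromosomes_share_nothing(self):
        assert overlap_length(iv(1, 100), iv(1, 100, chrom="chr2")) == 0

    def test_strand_is_ignored(self):
        assert overlap_length(iv(1, 100), iv(50, 150, strand="-")) == 51


class TestSpanSpanScore:
    def test_identical_spans_score_one(self):
        g = make_gene("a", [(1, 100)])
        h = make_gene("b", [(1, 100)], strand="-")
        assert span_span_score(g, h) == (1.0, 1.0, 1.0)

    def test_worked_half_overlap(self):
        """Spans [1,100] and [51,150]: P1 = P2 = 0.5, SS = 0.25."""
        g1 = make_gene("g1", [(1, 100)])
        g2 = make_gene("g2", [(51, 150)])
        p1, p2, ss = span_span_score(g1, g2)
        assert (p1, p2, ss) == (0.5, 0.5, 0.25)

    def test_disjoint_spans_score_zero(self):
        assert span_span_score(make_gene("a", [(1, 100)]), make_gene("b", [(200, 300)]))[2] == 0.0

    def test_different_chromosomes_score_zero_without_error(self):
        g = make_gene("a", [(1, 100)])
        h = make_gene("b", [(1, 100)], chrom="chr2")
        assert span_span_score(g, h)[2] == 0.0

    def test_monotone_in_overlap(self):
        # fixed span lengths, growing overlap region never decreases SS
        prev = -1.0
        for shift in range(100, -1, -10):
            ss = span_span_score(
                make_gene("a", [(1, 100)]), make_gene("b", [(1 + shift, 100 + shift)])
            )[2]
            assert ss >= prev
            prev = ss


class TestExonExonScore:
    def test_identical_single_exon_genes(self):
        g = make_gene("a", [(1, 100)])
        h = make_gene("b", [(1, 100)])
        pairs, te, ee = exon_exon_score(g, h)
        assert te == 1 and ee == 1.0 and len(pairs) == 1

    def test_worked_example(self):
        """Exons {[1,100],[201,300]} vs {[51,150]}: E=0.25, TE=2, EE=0.125."""
        g1 = make_gene("g1", [(1, 100), (201, 300)])
        g2 = make_gene("g2", [(51, 150)])
        pairs, te, ee = exon_exon_score(g1, g2)
        assert pairs == ((0, 0, 0.25),)
        assert te == 2
        assert ee == 0.125

    def test_identical_exon_structures_score_one(self):
        exons = [(10, 50), (120, 200), (400, 420)]
        assert exon_exon_score(make_gene("a", exons), make_gene("b", exons))[2] == 1.0

    def test_no_exon_overlap_scores_zero(self):
        g1 = make_gene("g1", [(1, 100), (300, 400)])
        g2 = make_gene("g2", [(150, 250)])
        pairs, te, ee = exon_exon_score(g1, g2)
        assert pairs == () and ee == 0.0
        assert te == 3  # both g2 exons counted: none shares coordinates

    def test_te_exclusion_identity_mode(self):
        # partial overlap: under identity reading the g2 exon still counts in TE
        g1 = make_gene("g1", [(1, 100)])
        g2 = make_gene("g2", [(51, 150)])
        _, te_overlap, _ = exon_exon_score(g1, g2, te_exclusion="overlap")
        _, te_identity, _ = exon_exon_score(g1, g2, te_exclusion="identity")
        assert te_overlap == 1 and te_identity == 2

    def test_ee_is_gene1_anchored(self):
        # two g1 exons (retained from different transcripts) hit one g2 exon:
        # TE = 2 anchored on g1 but 1 anchored on g2
        g1 = make_gene("g1", [(1, 100), (90, 200)])
        g2 = make_gene("g2", [(50, 150)])
        assert exon_exon_score(g1, g2)[2] != exon_exon_score(g2, g1)[2]


class TestRelativeOrientation:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("+", "+", Orientation.SENSE),
            ("+", "-", Orientation.ANTISENSE),
            ("-", "-", Orientation.SENSE),
            ("-", "+", Orientation.ANTISENSE),
        ],
    )
    def test_sense_iff_strands_equal(self, s1, s2, expected):
        g = make_gene("a", [(1, 10)], strand=s1)
        h = make_gene("b", [(5, 15)], strand=s2)
        assert relative_orientation(g, h) is expected


class TestOracleEquivalence:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(g1=gene_models(), g2=gene_models())
    def test_scores_match_per_base_oracle_and_bounds(self, g1, g2):
        p1, p2, ss = span_span_score(g1, g2)
        bp1, bp2, bss = brute_span_span(g1, g2)
        assert p1 == pytest.approx(bp1) and p2 == pytest.approx(bp2)
        assert ss == pytest.approx(bss)
        pairs, te, ee = exon_exon_score(g1, g2)
        bte, bee = brute_exon_exon(g1, g2)
        assert te == bte
        assert ee == pytest.approx(bee)
        assert 0.0 <= ss <= 1.0 and 0.0 <= ee <= 1.0
        assert te >= max(len(g1.exons), 1)
        assert all(0.0 <= e <= 1.0 for _, _, e in pairs)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(g1=gene_models(), g2=gene_models())
    def test_span_score_symmetry(self, g1, g2):
        assert span_span_score(g1, g2)[2] == pytest.approx(span_span_score(g2, g1)[2])
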