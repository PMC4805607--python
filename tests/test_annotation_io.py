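"""GTF/BED/TSV ingestion, gene-model assembly, and EST normalization."""

from __future__ import annotations

import pytest

from pseudolap.annotation_io import (
    GtfFormatError,
    deduplicate_ids,
    load_ests,
    normalize_est_orientation,
    read_gtf,
    read_point_features,
    write_gtf,
)
from pseudolap.models import EstRecord, ReadEnd, Strand

from conftest import make_gene


def gtf_line(
    chrom="chr1", feature="exon", start=100, end=200, strand="+",
    gene="G1", transcript="T1", extra="",
) -> str:
    return (
        f"{chrom}\ttest\t{feature}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{transcript}";{extra}\n'
    )


class TestReadGtf:
    def test_groups_exons_by_gene_and_derives_span(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line(start=100, end=200) + gtf_line(start=400, end=500))
        (model,) = read_gtf(p, "pg")
        assert model.gene_id == "G1"
        assert (model.span.start, model.span.end) == (100, 500)
        assert len(model.exons) == 2
        assert model.source == "pg"

    def test_two_transcripts_contribute_all_exons(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            gtf_line(start=100, end=200, transcript="T1")
            + gtf_line(start=150, end=300, transcript="T2")
        )
        (model,) = read_gtf(p, "pg")
        assert len(model.exons) == 2
        assert model.transcript_ids == frozenset({"T1", "T2"})

    def test_exons_sorted_by_start(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line(start=400, end=500) + gtf_line(start=100, end=200))
        (model,) = read_gtf(p, "pg")
        assert [e.start for e in model.exons] == [100, 400]

    def test_non_exon_features_ignored(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line(feature="CDS", start=1, end=50) + gtf_line())
        (model,) = read_gtf(p, "pg")
        assert (model.span.start, model.span.end) == (100, 200)

    def test_start_after_end_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text(gtf_line() + gtf_line(start=500, end=400))
        with pytest.raises(GtfFormatError, match=r":2:"):
            read_gtf(p, "pg")

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\ttest\texon\t1\t100\t.\t+\n",  # wrong column count
            gtf_line(strand="."),  # unknown strand
            'chr1\ttest\texon\t1\t100\t.\t+\t.\ttranscript_id "T";\n',  # no gene_id
        ],
    )
    def test_malformed_lines_rejected(self, tmp_path, line):
        p = tmp_path / "bad.gtf"
        p.write_text(line)
        with pytest.raises(GtfFormatError, match=r":1:"):
            read_gtf(p, "pg")

    def test_multi_strand_gene_split_with_suffixed_ids(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(gtf_line(strand="+") + gtf_line(start=400, end=500, strand="-"))
        models = read_gtf(p, "pg")
        assert sorted(m.gene_id for m in models) == ["G1#chr1#+", "G1#chr1#-"]

    def test_round_trip(self, tmp_path):
        genes = [
            make_gene("A", [(10, 50), (80, 120)], strand="-", source="pg"),
            make_gene("B", [(500, 700)], chrom="chr2", source="pg", note="x"),
        ]
        p = tmp_path / "out.gtf"
        write_gtf(genes, p)
        back = read_gtf(p, "pg")
        assert {m.gene_id for m in back} == {"A", "B"}
        by_id = {m.gene_id: m for m in back}
        for g in genes:
            assert by_id[g.gene_id].exons == g.exons
            assert by_id[g.gene_id].strand == g.strand


class TestDeduplicateIds:
    def test_identical_id_pairs_collapse_to_first(self):
        a = make_gene("G", [(1, 100)], transcripts={"T1"})
        b = make_gene("G", [(200, 300)], transcripts={"T1"})
        assert deduplicate_ids([a, b]) == [a]

    def test_all_unique_is_identity(self):
        models = [make_gene(f"G{i}", [(i * 10 + 1, i * 10 + 5)]) for i in range(5)]
        assert deduplicate_ids(models) == models

    def test_same_gene_id_disjoint_transcripts_both_kept(self):
        a = make_gene("G", [(1, 100)], transcripts={"T1"})
        b = make_gene("G", [(1, 100)], transcripts={"T2"})
        assert deduplicate_ids([a, b]) == [a, b]

    def test_idempotent(self):
        models = [
            make_gene("G", [(1, 100)], transcripts={"T1"}),
            make_gene("G", [(1, 100)], transcripts={"T1"}),
            make_gene("H", [(1, 100)]),
        ]
        once = deduplicate_ids(models)
        assert deduplicate_ids(once) == once


class TestEstNormalization:
    def test_three_prime_est_strand_flipped(self):
        m = make_gene("E", [(1, 100), (200, 300)], strand="+")
        out = normalize_est_orientation(EstRecord(m, ReadEnd.THREE_PRIME))
        assert out.strand is Strand.MINUS
        assert [(e.start, e.end) for e in out.exons] == [(1, 100), (200, 300)]

    @pytest.mark.parametrize("end", [ReadEnd.FIVE_PRIME, ReadEnd.UNKNOWN])
    def test_other_read_ends_unchanged(self, end):
        m = make_gene("E", [(1, 100)], strand="+")
        assert normalize_est_orientation(EstRecord(m, end)).strand is Strand.PLUS

    def test_flip_is_involutive(self):
        m = make_gene("E", [(1, 100)], strand="-")
        once = normalize_est_orientation(EstRecord(m, ReadEnd.THREE_PRIME))
        twice = normalize_est_orientation(EstRecord(once, ReadEnd.THREE_PRIME))
        assert twice.strand is Strand.MINUS

    def test_load_ests_reads_attribute(self, tmp_path):
        p = tmp_path / "est.gtf"
        p.write_text(
            gtf_line(gene="E1", extra=' read_end "3prime";')
            + gtf_line(gene="E2", start=400, end=500, extra=' read_end "5prime";')
        )
        models = {m.gene_id: m for m in load_ests(p)}
        assert models["E1"].strand is Strand.MINUS
        assert models["E2"].strand is Strand.PLUS


class TestPointFeatures:
    def test_bed_converted_to_one_based(self, tmp_path):
        p = tmp_path / "pi.bed"
        p.write_text("chr1\t99\t100\tpi1\n")
        (f,) = read_point_features(p, "bed")
        assert (f.chrom, f.start, f.end, f.feature_id) == ("chr1", 100, 100, "pi1")

    def test_tsv_row_with_trait_payload(self, tmp_path):
        p = tmp_path / "snp.tsv"
        p.write_text("rs42\tchr2\t12345\tmelanoma\n")
        (f,) = read_point_features(p, "tsv")
        assert (f.feature_id, f.chrom, f.position, f.payload) == (
            "rs42", "chr2", 12345, "melanoma",
        )

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_point_features(p, "bed") == []

    def test_bad_column_mapping_is_configuration_error(self, tmp_path):
        p = tmp_path / "snp.tsv"
        p.write_text("rs42\tchr2\t12345\n")
        with pytest.raises(ValueError, match="column mapping"):
            read_point_features(p, "tsv", columns={"id": 0, "chrom": 1, "pos": 9})
        with pytest.raises(ValueError, match="missing required key"):
            read_point_features(p, "tsv", columns={"id": 0})
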