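"""Coordinate conventions, domain invariants, and table round-trips."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from baitpond import io as bpio
from baitpond.intervals import GenomicInterval, normalize_chrom
from baitpond.records import (
    GeneModel,
    LeadSnp,
    TranscriptModel,
    VariationRecord,
    VariationType,
    parse_vtype,
)


class TestGenomicInterval:
    def test_inclusive_length(self):
        assert GenomicInterval("1", 100, 100).length == 1
        assert GenomicInterval("22", 37723443, 37724117).length == 675

    @pytest.mark.parametrize(
        "chrom,start,end",
        [("1", 0, 10), ("1", 5, 4), ("", 1, 2)],
    )
    def test_invalid_intervals_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_chr_prefix_stripped(self):
        assert GenomicInterval("chr3", 1, 2).chrom == "3"
        assert normalize_chrom("chrX") == "X"

    @given(
        a=st.integers(1, 10_000),
        la=st.integers(0, 500),
        b=st.integers(1, 10_000),
        lb=st.integers(0, 500),
    )
    def test_overlap_symmetric_and_matches_gap(self, a, la, b, lb):
        x = GenomicInterval("1", a, a + la)
        y = GenomicInterval("1", b, b + lb)
        assert x.overlaps(y) == y.overlaps(x)
        assert x.overlaps(y) == (x.gap_to(y) == 0)

    @given(
        start=st.integers(1, 10**6),
        length=st.integers(1, 10**4),
        bucket=st.integers(1, 5000),
    )
    def test_bucket_range_covers_span(self, start, length, bucket):
        iv = GenomicInterval("2", start, start + length - 1)
        lo, hi = iv.bucket_range(bucket)
        assert lo <= start // bucket <= hi
        assert lo <= (start + length - 1) // bucket <= hi


class TestVariationRecord:
    def test_point_anchored_hcondel(self):
        # one human anchor coordinate, multi-kb ancestral length
        rec = VariationRecord(
            var_id="KDM4A:hCONDEL:43656932",
            vtype=VariationType.HCONDEL,
            locus=GenomicInterval("1", 43656932, 43656932),
            length_bp=466,
        )
        assert rec.locus.is_point and rec.span_matches_length

    def test_size_rules(self):
        small_ins = VariationRecord(
            "v1", VariationType.INSERTION, GenomicInterval("1", 10, 49), 40
        )
        assert not small_ins.admissible_to_pond()
        hsd = VariationRecord(
            "v2", VariationType.HSD, GenomicInterval("1", 1, 1200), 1200
        )
        assert hsd.admissible_to_pond()

    def test_vtype_aliases(self):
        assert parse_vtype("hCONDEL") is VariationType.HCONDEL
        assert parse_vtype("STR expansion") is VariationType.STR_EXPANSION
        assert parse_vtype("SV-d") is VariationType.DELETION
        with pytest.raises(ValueError):
            parse_vtype("retro-transposition")


class TestTranscriptInvariants:
    def _exons(self, *pairs):
        return tuple(GenomicInterval("1", a, b, "+") for a, b in pairs)

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            TranscriptModel(
                "t1", "G", "human", "protein_coding",
                self._exons((1, 100), (90, 200)),
            )

    def test_processed_transcript_cannot_have_cds(self):
        with pytest.raises(ValueError):
            TranscriptModel(
                "t1", "G", "human", "processed_transcript",
                self._exons((1, 100), (200, 300)),
                cds=GenomicInterval("1", 50, 250),
            )

    def test_gene_requires_transcripts_inside_span(self):
        t = TranscriptModel(
            "t1", "G", "human", "protein_coding",
            self._exons((100, 200), (300, 400)),
            cds=GenomicInterval("1", 150, 350),
        )
        with pytest.raises(ValueError):
            GeneModel("G", GenomicInterval("1", 100, 350), (t,))
        GeneModel("G", GenomicInterval("1", 100, 400), (t,))  # fits


class TestTables:
    def test_catalog_row_parses_as_point_hcondel(self, catalog):
        rec = next(v for v in catalog.variations if v.var_id.startswith("KDM4A"))
        assert rec.vtype is VariationType.HCONDEL
        assert rec.locus == GenomicInterval("1", 43656932, 43656932)
        assert rec.length_bp == 466

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        bpio.write_table([], p, schema="pond")
        assert bpio.read_table(p, "pond") == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("rsid\tchrom\n")
        with pytest.raises(bpio.SchemaError, match="missing column"):
            bpio.read_table(p, "lead_snps")

    def test_bad_coordinate_names_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "var_id\tchrom\tstart\tend\ttype\tlength\tsource\n"
            "v1\t1\t100\t200\thCONDEL\t100\ts\n"
            "v2\t1\tNOTANUMBER\t200\thCONDEL\t100\ts\n"
        )
        with pytest.raises(bpio.TableParseError, match="line 3"):
            bpio.read_table(p, "pond")

    @pytest.mark.parametrize("schema", ["lead_snps", "bait", "pond", "prey", "calls", "hieg"])
    def test_round_trip_every_schema(self, schema, tmp_path, catalog, small_sim):
        from baitpond.bait import integrate_bait_genes
        from baitpond.hieg import select_hiegs
        from baitpond.overlap import kb_bucket_overlap

        cfg, genome, inputs = small_sim
        bait, _ = integrate_bait_genes(inputs.lead_snps, genome.genes)
        if schema == "lead_snps":
            records = inputs.lead_snps
        elif schema == "bait":
            records = bait
        elif schema == "pond":
            records = list(catalog.variations)
        elif schema == "prey":
            records = kb_bucket_overlap(
                [r for rs in inputs.pond_sources.values() for r in rs], bait
            )
        elif schema == "calls":
            records = list(catalog.calls)
        else:
            records, _ = select_hiegs(list(catalog.calls), list(catalog.variations))
        p = tmp_path / f"{schema}.tsv"
        bpio.write_table(records, p, schema=schema)
        assert bpio.read_table(p, schema) == list(records)

    def test_catalog_round_trip_row_count(self, tmp_path, catalog):
        p = tmp_path / "catalog.tsv"
        bpio.write_table(list(catalog.variations), p)
        assert len(bpio.read_table(p, "pond")) == 47

    def test_bed_half_open_conversion(self, tmp_path):
        # 0-based half-open BED becomes a 176-bp 1-based inclusive span
        p = tmp_path / "in.bed"
        p.write_text("chr3\t48968204\t48968380\n")
        (rec,) = bpio.read_bed_variations(p, "insertion")
        assert rec.locus == GenomicInterval("3", 48968205, 48968380)
        assert rec.length_bp == 176


class TestGff3:
    def test_round_trip(self, small_sim, tmp_path):
        _, genome, _ = small_sim
        path = tmp_path / "genes.gff3"
        bpio.write_gff3(genome.genes, path)
        back = bpio.read_gff3(path)
        assert {g.symbol for g in back} == {g.symbol for g in genome.genes}
        orig = {g.symbol: g for g in genome.genes}
        for g in back:
            o = orig[g.symbol]
            assert g.span == o.span
            assert {t.transcript_id for t in g.transcripts} == {
                t.transcript_id for t in o.transcripts
            }
            for t in g.transcripts:
                ot = next(x for x in o.transcripts if x.transcript_id == t.transcript_id)
                assert t.exons == ot.exons
                assert t.biotype == ot.biotype
                assert t.principal == ot.principal
                assert (t.cds is None) == (ot.cds is None)
                if t.cds is not None:
                    assert (t.cds.start, t.cds.end) == (ot.cds.start, ot.cds.end)


class TestLeadSnpInvariants:
    def test_point_locus_required(self):
        with pytest.raises(ValueError):
            LeadSnp("rs1", GenomicInterval("1", 10, 20), "s1", "G")

    def test_p_value_range(self):
        with pytest.raises(ValueError):
            LeadSnp("rs1", GenomicInterval("1", 10, 10), "s1", "G", p_value=1.5)
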