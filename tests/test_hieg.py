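"""Gene-structure classification, exon gain/loss, and HIEG selection rules."""

import pytest

from baitpond.hieg import (
    AnnotationError,
    check_inversion_breakpoints,
    classify_position,
    detect_exon_gain_loss,
    select_hiegs,
)
from baitpond.intervals import GenomicInterval
from baitpond.records import (
    GeneModel,
    HiegCategory,
    PositionalCall,
    PositionalClass,
    TranscriptModel,
    VariationRecord,
    VariationType,
)


def _iv(start, end, chrom="1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def _two_exon_gene(strand="+"):
    t = TranscriptModel(
        "t1", "G", "human", "protein_coding",
        exons=(_iv(1000, 1400, strand=strand), _iv(2000, 2400, strand=strand)),
        cds=_iv(1200, 2200, strand=strand),
        principal=True,
    )
    return GeneModel("G", _iv(1000, 2400, strand=strand), (t,))


def _var(var_id, start, end, vtype=VariationType.INSERTION, length=None, **kw):
    return VariationRecord(var_id, vtype, _iv(start, end), length or (end - start + 1), **kw)


class TestClassifyPosition:
    def test_cds_exon(self):
        call = classify_position(_var("v", 1250, 1320), _two_exon_gene())
        assert call.pclass is PositionalClass.CDS_EXON
        assert call.nearest_exon_distance == 0
        assert call.isoform_id == "t1"

    @pytest.mark.parametrize(
        "strand,expected_first,expected_last",
        [("+", PositionalClass.UTR5, PositionalClass.UTR3),
         ("-", PositionalClass.UTR3, PositionalClass.UTR5)],
    )
    def test_utr_sides_strand_aware(self, strand, expected_first, expected_last):
        gene = _two_exon_gene(strand)
        assert classify_position(_var("a", 1050, 1100), gene).pclass is expected_first
        assert classify_position(_var("b", 2300, 2350), gene).pclass is expected_last

    def test_intronic_variation_with_distance(self):
        call = classify_position(_var("v", 1500, 1600), _two_exon_gene())
        assert call.pclass is PositionalClass.INTRON
        # 1500 - 1400 = 100 vs 2000 - 1600 = 400
        assert call.nearest_exon_distance == 100

    def test_noncoding_isoform_exon_beats_intron(self):
        coding = _two_exon_gene().transcripts[0]
        processed = TranscriptModel(
            "t0", "G", "human", "processed_transcript",
            exons=(_iv(1600, 1800), _iv(2000, 2400)),
        )
        gene = GeneModel("G", _iv(1000, 2400), (coding, processed))
        call = classify_position(_var("v", 1650, 1700), gene)
        assert call.pclass is PositionalClass.NONCODING_EXON
        assert call.isoform_id == "t0"

    def test_flank_for_bucket_only_hit(self):
        call = classify_position(_var("v", 2500, 2600), _two_exon_gene())
        assert call.pclass is PositionalClass.FLANK
        assert call.nearest_exon_distance == 100

    def test_planted_classes_recovered(self, small_sim):
        cfg, genome, inputs = small_sim
        genes = {g.symbol: g for g in genome.genes}
        by_id = {r.var_id: r for rs in inputs.pond_sources.values() for r in rs}
        prey = {g: v for g, v in inputs.truth.expected_prey}
        bait_symbols = sorted(
            bp.gene.symbol for bp in genome.blueprints[: cfg.n_bait]
        )
        ordered = [bp.gene.symbol for bp in genome.blueprints[: cfg.n_bait]]
        for gene_idx, vtype, pclass in cfg.planted_hieg_spec:
            symbol = ordered[gene_idx]
            var = by_id[prey[symbol]]
            assert var.vtype is vtype
            call = classify_position(var, genes[symbol])
            assert call.pclass is pclass, (symbol, vtype, call)
        assert set(ordered) == set(bait_symbols)


class TestExonGainLoss:
    def _transcripts(self, with_extra_exon):
        exons = [_iv(1000, 1100), _iv(2000, 2100), _iv(3000, 3100)]
        if with_extra_exon:
            exons.insert(2, _iv(2500, 2559))  # the 60-bp gained exon
        return TranscriptModel(
            "tv" if with_extra_exon else "tp", "G", "human", "protein_coding",
            exons=tuple(exons), cds=_iv(1050, 3050), principal=not with_extra_exon,
        )

    def _seqs(self, rng_seed=0):
        import numpy as np

        rng = np.random.default_rng(rng_seed)
        seqs = {}
        pool = {}
        for t in self._all:
            for e in t.exons:
                key = (e.start, e.end)
                if key not in pool:
                    pool[key] = "".join(rng.choice(list("ACGT"), size=e.length))
                seqs[(t.transcript_id, e.start, e.end)] = pool[key]
        return seqs

    def test_gained_exon_detected_only_in_human(self):
        principal = self._transcripts(False)
        variant = self._transcripts(True)
        ape = TranscriptModel(
            "ta", "G", "chimpanzee", "protein_coding",
            exons=principal.exons, cds=principal.cds, principal=True,
        )
        self._all = [principal, variant, ape]
        events = detect_exon_gain_loss(
            "G", [principal, variant], {"chimpanzee": [ape]}, self._seqs()
        )
        assert [(e.event, e.length_bp) for e in events] == [
            (VariationType.EXON_GAIN, 60)
        ]

    def test_identical_exon_sets_give_no_events(self):
        principal = self._transcripts(False)
        ape = TranscriptModel(
            "ta", "G", "gorilla", "protein_coding",
            exons=principal.exons, cds=principal.cds, principal=True,
        )
        self._all = [principal, ape]
        assert detect_exon_gain_loss("G", [principal], {"gorilla": [ape]}, self._seqs()) == []

    def test_antisymmetric_under_role_swap(self):
        principal = self._transcripts(False)
        variant = self._transcripts(True)
        ape = TranscriptModel(
            "ta", "G", "chimpanzee", "protein_coding",
            exons=principal.exons, cds=principal.cds, principal=True,
        )
        self._all = [principal, variant, ape]
        seqs = self._seqs()
        gains = detect_exon_gain_loss("G", [principal, variant], {"chimpanzee": [ape]}, seqs)
        swapped = detect_exon_gain_loss("G", [ape], {"chimpanzee": [principal, variant]}, seqs)
        assert [e.event for e in gains] == [VariationType.EXON_GAIN]
        assert [e.event for e in swapped] == [VariationType.EXON_LOSS]
        assert gains[0].exon == swapped[0].exon

    def test_missing_exon_sequence_names_the_transcript(self):
        principal = self._transcripts(False)
        with pytest.raises(AnnotationError, match="tp"):
            detect_exon_gain_loss("G", [principal], {}, {})


class TestSelectHiegs:
    def test_catalog_selection(self, catalog):
        hiegs, counts = select_hiegs(list(catalog.calls), list(catalog.variations))
        assert len(hiegs) == 40
        assert {c.value: n for c, n in counts.items()} == {
            "exon_gain_loss": 2, "hCONDEL": 28, "HSD": 1, "indel": 8, "STR": 4,
        }
        dual = sorted(h.gene_symbol for h in hiegs if len(h.categories) >= 2)
        assert dual == ["AFF3", "GNB5", "NRXN1"]

    def test_category_sum_identity(self, catalog):
        # category slots = unique genes + genes carrying two categories
        hiegs, counts = select_hiegs(list(catalog.calls), list(catalog.variations))
        n_multi = sum(len(h.categories) - 1 for h in hiegs)
        assert sum(counts.values()) == len(hiegs) + n_multi

    def test_insertion_also_str_counts_as_str_not_indel(self):
        var = _var("a", 1000, 1175, VariationType.INSERTION, also_str=True)
        call = PositionalCall("ARIH2", "a", PositionalClass.NONCODING_EXON)
        hiegs, counts = select_hiegs([call], [var])
        assert hiegs[0].categories == frozenset({HiegCategory.STR})
        assert counts[HiegCategory.INDEL] == 0

    def test_intronic_indels_do_not_admit(self):
        vars_ = [_var(f"v{i}", 1000 + i * 10, 1060 + i * 10) for i in range(3)]
        calls = [
            PositionalCall(f"G{i}", v.var_id, PositionalClass.INTRON)
            for i, v in enumerate(vars_)
        ]
        hiegs, counts = select_hiegs(calls, vars_)
        assert hiegs == [] and sum(counts.values()) == 0

    def test_intronic_hcondel_admits_regardless(self):
        var = _var("h", 1500, 1500, VariationType.HCONDEL, length=700)
        call = PositionalCall("G", "h", PositionalClass.INTRON, 31)
        hiegs, _ = select_hiegs([call], [var])
        assert hiegs[0].categories == frozenset({HiegCategory.HCONDEL})
        assert "regardless" in hiegs[0].admit_rule

    def test_unknown_variation_reference_is_error(self):
        with pytest.raises(AnnotationError, match="unknown variation"):
            select_hiegs([PositionalCall("G", "ghost", PositionalClass.INTRON)], [])

    def test_prey_hits_must_be_covered_by_calls(self):
        from baitpond.records import PreyHit

        var = _var("v", 100, 160)
        with pytest.raises(AnnotationError, match="without positional calls"):
            select_hiegs([], [var], prey=[PreyHit("G", "v", "kb_bucket", True)])


class TestInversionAudit:
    def _gene(self, symbol, start, end):
        t = TranscriptModel(
            f"{symbol}.t", symbol, "human", "protein_coding",
            exons=(_iv(start, start + 100), _iv(end - 100, end)),
            cds=_iv(start + 50, end - 50),
        )
        return GeneModel(symbol, _iv(start, end), (t,))

    def _inv(self, var_id, start, end):
        return _var(var_id, start, end, VariationType.INVERSION)

    def test_gene_inside_inversion(self):
        status = check_inversion_breakpoints(
            [self._inv("i", 100000, 200000)], [self._gene("G", 150000, 160000)]
        )
        assert status == {"G": "inside"}

    def test_gene_containing_breakpoint(self):
        status = check_inversion_breakpoints(
            [self._inv("i", 100000, 200000)], [self._gene("G", 95000, 105000)]
        )
        assert status == {"G": "at_breakpoint"}

    def test_gene_elsewhere_is_outside(self):
        status = check_inversion_breakpoints(
            [self._inv("i", 100000, 200000)], [self._gene("G", 300000, 310000)]
        )
        assert status == {"G": "outside"}

    def test_planted_inversion_genes_never_at_breakpoint(self, small_sim):
        # mirrors the published audit: every inversion-hit gene lies interior
        _, genome, inputs = small_sim
        invs = inputs.pond_sources[VariationType.INVERSION]
        statuses = check_inversion_breakpoints(invs, genome.genes)
        hit_genes = {
            g for g, v in inputs.truth.expected_prey if v.startswith("inversion")
        }
        assert hit_genes  # the small preset plants inversion-hit genes
        for g in hit_genes:
            assert statuses[g] == "inside"
        assert sum(1 for s in statuses.values() if s == "at_breakpoint") == 0
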