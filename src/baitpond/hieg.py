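"""HIEG selection: gene-structure classification and admission rules.

A prey gene becomes a human intelligence evolution gene (HIEG) when the
variation it carries plausibly touches gene output:

* rule (a): the variation lies in exonic sequence of *any* isoform — a CDS
  exon, a UTR, or an exon of a non-protein-coding isoform (processed
  transcript).  "Coding region" is read this inclusive way because the
  published HIEG set itself admits 3'UTR insertions and processed-
  transcript exons;
* rule (b): the variation is an hCONDEL, an HSD, or an exon gain/loss —
  these admit their gene regardless of intronic position, hCONDELs for
  their strong lineage specificity and HSD/exon events for their intrinsic
  structural consequence.

Categories follow the variation type, with one precedence rule: an
insertion also called as an STR expansion counts under STR, not indel.
Inversions never admit a gene; they are audited separately for whether any
gene sits on an inversion breakpoint.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .alignment import (
    DEFAULT_MIN_COVERAGE,
    DEFAULT_MIN_IDENTITY,
    segment_found,
)
from .intervals import GenomicInterval
from .pond import VariationPond
from .records import (
    EXONIC_CLASSES,
    PCLASS_PRECEDENCE,
    GeneModel,
    HiegCategory,
    HiegRecord,
    PositionalCall,
    PositionalClass,
    PreyHit,
    TranscriptModel,
    VariationRecord,
    VariationType,
)


class AnnotationError(ValueError):
    pass


def _utr_side(pos_lo: int, pos_hi: int, t: TranscriptModel) -> PositionalClass:
    """UTR side of an exonic, non-CDS overlap, resolved strand-aware."""
    assert t.cds is not None
    before_cds = pos_lo < t.cds.start
    if t.strand == "-":
        return PositionalClass.UTR3 if before_cds else PositionalClass.UTR5
    return PositionalClass.UTR5 if before_cds else PositionalClass.UTR3


def _classify_in_transcript(
    var: GenomicInterval, t: TranscriptModel
) -> Optional[PositionalClass]:
    """Positional class of *var* within one transcript, or None if outside it."""
    overlapped = [e for e in t.exons if var.overlaps(e)]
    if overlapped:
        if t.cds is None:
            return PositionalClass.NONCODING_EXON
        for e in overlapped:
            lo, hi = max(e.start, t.cds.start), min(e.end, t.cds.end)
            if lo <= hi and var.start <= hi and lo <= var.end:
                return PositionalClass.CDS_EXON
        # exonic but entirely outside the CDS: a UTR
        e = overlapped[0]
        return _utr_side(max(var.start, e.start), min(var.end, e.end), t)
    if var.overlaps(t.span):
        return PositionalClass.INTRON
    return None


def classify_position(
    var: VariationRecord, gene: GeneModel, species: str = "human"
) -> PositionalCall:
    """Resolve where a variation falls in a gene, across all isoforms.

    Each isoform is classified independently and the most consequential
    class wins: CDS exon > UTR > non-coding-isoform exon > intron > flank.
    ``nearest_exon_distance`` is the smallest gap to any exon of any
    isoform (0 when the variation overlaps an exon; adjacent bases are 1).
    """
    transcripts = gene.transcripts_of(species) or gene.transcripts
    if not transcripts:
        raise AnnotationError(f"gene {gene.symbol} has no transcripts")
    best: Optional[PositionalClass] = None
    best_isoform = ""
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        pclass = _classify_in_transcript(var.locus, t)
        if pclass is None:
            continue
        if best is None or PCLASS_PRECEDENCE[pclass] > PCLASS_PRECEDENCE[best]:
            best, best_isoform = pclass, t.transcript_id
    if best is None:
        if var.locus.overlaps(gene.span):
            # intragenic but between transcript spans
            best = PositionalClass.INTRON
        else:
            best = PositionalClass.FLANK
    distance = min(
        (var.locus.gap_to(e) for t in transcripts for e in t.exons
         if e.chrom == var.locus.chrom),
        default=0,
    )
    return PositionalCall(
        gene_symbol=gene.symbol,
        var_id=var.var_id,
        pclass=best,
        nearest_exon_distance=distance,
        isoform_id=best_isoform,
    )


# ---------------------------------------------------------------------------
# Cross-species exon gain/loss


@dataclass(frozen=True)
class ExonEvent:
    """A human-specific exon gain, or an ape exon lost from human isoforms."""

    event: VariationType  # EXON_GAIN | EXON_LOSS
    gene_symbol: str
    transcript_id: str
    exon: GenomicInterval
    length_bp: int
    species: str  # carrier of the exon ("human" for gains)


ExonSeqMap = Mapping[tuple[str, int, int], str]


def _exon_seq(seqs: ExonSeqMap, t: TranscriptModel, e: GenomicInterval) -> str:
    key = (t.transcript_id, e.start, e.end)
    if key not in seqs:
        raise AnnotationError(
            f"missing sequence for exon {e.start}-{e.end} of transcript {t.transcript_id}"
        )
    return seqs[key]


def _matches_any(seq: str, others: Sequence[str], min_identity: float, min_coverage: float) -> bool:
    return any(
        segment_found(seq, other, min_identity, min_coverage) for other in others
    )


def detect_exon_gain_loss(
    gene_symbol: str,
    human_transcripts: Sequence[TranscriptModel],
    ape_transcripts: Mapping[str, Sequence[TranscriptModel]],
    exon_sequences: ExonSeqMap,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> list[ExonEvent]:
    """Find exons private to human isoforms (gain) or to ape isoforms (loss).

    A human exon is a gain iff its sequence matches no exon of any
    transcript of the gene in *any* supplied ape species (match =
    >= ``min_identity`` identity over >= ``min_coverage`` of the exon, by
    local alignment).  Loss is symmetric: an ape exon matched by no human
    exon of any isoform.  Events are deduplicated by exon sequence.
    """
    human_seqs: dict[str, tuple[TranscriptModel, GenomicInterval]] = {}
    for t in human_transcripts:
        for e in t.exons:
            human_seqs.setdefault(_exon_seq(exon_sequences, t, e), (t, e))
    ape_seqs_by_species: dict[str, dict[str, tuple[TranscriptModel, GenomicInterval]]] = {}
    for species, transcripts in ape_transcripts.items():
        pool: dict[str, tuple[TranscriptModel, GenomicInterval]] = {}
        for t in transcripts:
            for e in t.exons:
                pool.setdefault(_exon_seq(exon_sequences, t, e), (t, e))
        ape_seqs_by_species[species] = pool
    events: list[ExonEvent] = []
    all_ape_seqs = [s for pool in ape_seqs_by_species.values() for s in pool]
    for seq, (t, e) in human_seqs.items():
        if ape_seqs_by_species and not _matches_any(
            seq, all_ape_seqs, min_identity, min_coverage
        ):
            events.append(
                ExonEvent(
                    event=VariationType.EXON_GAIN,
                    gene_symbol=gene_symbol,
                    transcript_id=t.transcript_id,
                    exon=e,
                    length_bp=e.length,
                    species="human",
                )
            )
    seen_lost: set[str] = set()
    for species, pool in ape_seqs_by_species.items():
        for seq, (t, e) in pool.items():
            if seq in seen_lost:
                continue
            if not _matches_any(seq, list(human_seqs), min_identity, min_coverage):
                seen_lost.add(seq)
                events.append(
                    ExonEvent(
                        event=VariationType.EXON_LOSS,
                        gene_symbol=gene_symbol,
                        transcript_id=t.transcript_id,
                        exon=e,
                        length_bp=e.length,
                        species=species,
                    )
                )
    return events


# ---------------------------------------------------------------------------
# Selection


_ALWAYS_ADMIT = {
    VariationType.HCONDEL: HiegCategory.HCONDEL,
    VariationType.HSD: HiegCategory.HSD,
    VariationType.EXON_GAIN: HiegCategory.EXON_GAIN_LOSS,
    VariationType.EXON_LOSS: HiegCategory.EXON_GAIN_LOSS,
}


def _category_of(var: VariationRecord, exon_located: bool) -> Optional[HiegCategory]:
    if var.vtype in _ALWAYS_ADMIT:
        return _ALWAYS_ADMIT[var.vtype]
    if not exon_located:
        return None
    if var.vtype in (VariationType.STR_CONTRACTION, VariationType.STR_EXPANSION):
        return HiegCategory.STR
    if var.vtype is VariationType.INSERTION and var.also_str:
        return HiegCategory.STR
    if var.vtype in (VariationType.INSERTION, VariationType.DELETION):
        return HiegCategory.INDEL
    return None  # exon-located inversions are audited, not admitted


def select_hiegs(
    calls: Sequence[PositionalCall],
    pond: VariationPond | Sequence[VariationRecord] | Mapping[str, VariationRecord],
    prey: Optional[Sequence[PreyHit]] = None,
) -> tuple[list[HiegRecord], dict[HiegCategory, int]]:
    """Apply the HIEG admission and category rules; dedupe by gene.

    Returns the HIEG records (sorted by gene symbol) and the per-category
    distinct-gene counts.  When *prey* is given, every hit must be covered
    by a positional call.
    """
    if isinstance(pond, Mapping):
        by_id = dict(pond)
    elif isinstance(pond, VariationPond):
        by_id = pond.by_id()
    else:
        by_id = {r.var_id: r for r in pond}
    call_index = {(c.gene_symbol, c.var_id): c for c in calls}
    if prey is not None:
        uncovered = [
            (h.gene_symbol, h.var_id)
            for h in prey
            if (h.gene_symbol, h.var_id) not in call_index
        ]
        if uncovered:
            raise AnnotationError(f"prey hits without positional calls: {uncovered[:5]}")
    per_gene: dict[str, dict] = defaultdict(
        lambda: {"vars": [], "cats": set(), "rules": set()}
    )
    for c in calls:
        if c.var_id not in by_id:
            raise AnnotationError(
                f"call for {c.gene_symbol} references unknown variation {c.var_id!r}"
            )
        var = by_id[c.var_id]
        cat = _category_of(var, exon_located=c.pclass in EXONIC_CLASSES)
        if cat is None:
            continue
        slot = per_gene[c.gene_symbol]
        slot["vars"].append(c.var_id)
        slot["cats"].add(cat)
        if var.vtype in _ALWAYS_ADMIT:
            slot["rules"].add(f"{var.vtype.value} (admitted regardless of position)")
        else:
            slot["rules"].add(f"exon-located {var.vtype.value} ({c.pclass.value})")
    records = [
        HiegRecord(
            gene_symbol=symbol,
            variations=tuple(dict.fromkeys(slot["vars"])),
            categories=frozenset(slot["cats"]),
            admit_rule="; ".join(sorted(slot["rules"])),
        )
        for symbol, slot in sorted(per_gene.items())
    ]
    category_counts: dict[HiegCategory, int] = {c: 0 for c in HiegCategory}
    for r in records:
        for c in r.categories:
            category_counts[c] += 1
    return records, category_counts


# ---------------------------------------------------------------------------
# Inversion breakpoint audit


def check_inversion_breakpoints(
    inversions: Sequence[VariationRecord],
    genes: Sequence[GeneModel] | Sequence[object],
) -> dict[str, str]:
    """Classify each gene against the inversion set.

    ``at_breakpoint``: the gene span contains an inversion endpoint;
    ``inside``: the gene lies wholly within some inversion (and touches no
    breakpoint); ``outside`` otherwise.  Accepts gene models or bait genes
    (anything with ``symbol`` and ``span``).
    """
    out: dict[str, str] = {}
    for g in genes:
        span: GenomicInterval = g.span
        status = "outside"
        for inv in inversions:
            if inv.vtype is not VariationType.INVERSION:
                raise ValueError(f"{inv.var_id} is not an inversion")
            if inv.locus.chrom != span.chrom:
                continue
            if span.contains_point(inv.locus.start) or span.contains_point(inv.locus.end):
                status = "at_breakpoint"
                break
            if inv.locus.contains(span):
                status = "inside"
        out[g.symbol] = status
    return out
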