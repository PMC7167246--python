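"""Domain records: GWAS leads, gene models, and typed human-specific variations."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .intervals import AUTOSOMES, GenomicInterval

SPECIES = ("human", "chimpanzee", "gorilla", "orangutan", "gibbon", "macaque")

#: Minimum length for an insertion/deletion to enter the variation pond.
INDEL_MIN_BP = 50
#: Minimum length of a human-specific segmental duplication (>1 kb, >90% similarity).
HSD_MIN_BP = 1000


class VariationType(enum.Enum):
    """Classes of human-specific structural variation relative to the great apes."""

    STR_CONTRACTION = "STR_contraction"
    STR_EXPANSION = "STR_expansion"
    INSERTION = "insertion"
    DELETION = "deletion"
    HCONDEL = "hCONDEL"
    HSD = "HSD"
    INVERSION = "inversion"
    EXON_GAIN = "exon_gain"
    EXON_LOSS = "exon_loss"

    def __str__(self) -> str:
        return self.value


_VTYPE_ALIASES = {
    "str-c": VariationType.STR_CONTRACTION,
    "str contraction": VariationType.STR_CONTRACTION,
    "str_contraction": VariationType.STR_CONTRACTION,
    "str-e": VariationType.STR_EXPANSION,
    "str expansion": VariationType.STR_EXPANSION,
    "str_expansion": VariationType.STR_EXPANSION,
    "insertion": VariationType.INSERTION,
    "ins": VariationType.INSERTION,
    "sv-i": VariationType.INSERTION,
    "deletion": VariationType.DELETION,
    "del": VariationType.DELETION,
    "sv-d": VariationType.DELETION,
    "hcondel": VariationType.HCONDEL,
    "hsd": VariationType.HSD,
    "inversion": VariationType.INVERSION,
    "inv": VariationType.INVERSION,
    "exon_gain": VariationType.EXON_GAIN,
    "exon gain": VariationType.EXON_GAIN,
    "exon_loss": VariationType.EXON_LOSS,
    "exon loss": VariationType.EXON_LOSS,
}


def parse_vtype(label: str) -> VariationType:
    """Map a free-form variation-type label to a :class:`VariationType`."""
    key = str(label).strip().lower().replace("(str expansion)", "").strip()
    if key in _VTYPE_ALIASES:
        return _VTYPE_ALIASES[key]
    raise ValueError(f"unknown variation type label: {label!r}")


VALIDATION_STATES = ("pending", "validated", "rejected")


@dataclass(frozen=True)
class GwasStudy:
    """One published GWAS or GWAS meta-analysis contributing lead SNPs."""

    study_id: str
    phenotype: str
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("sample size n must be positive")


@dataclass(frozen=True)
class LeadSnp:
    """An independent, genome-wide-significant lead SNP with its nearest gene.

    ``locus_id`` groups lead SNPs into association loci; when absent each
    SNP is its own locus.
    """

    rsid: str
    locus: GenomicInterval
    study_id: str
    nearest_gene: str
    p_value: Optional[float] = None
    locus_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.locus.is_point:
            raise ValueError(f"lead SNP {self.rsid} locus must be a point")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"lead SNP {self.rsid} p-value must be in (0, 1]")

    @property
    def effective_locus_id(self) -> str:
        return self.locus_id if self.locus_id else self.rsid


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: ordered exon blocks plus an optional CDS span."""

    transcript_id: str
    gene_symbol: str
    species: str
    biotype: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None
    principal: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.biotype not in ("protein_coding", "processed_transcript"):
            raise ValueError(f"unsupported biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.chrom != b.chrom:
                raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} exons overlap or are unsorted"
                )
        if self.biotype == "processed_transcript" and self.cds is not None:
            raise ValueError(
                f"processed transcript {self.transcript_id} must not carry a CDS"
            )
        if self.cds is not None:
            if not (self.span.start <= self.cds.start and self.cds.end <= self.span.end):
                raise ValueError(f"CDS outside exon span in {self.transcript_id}")
            for edge in (self.cds.start, self.cds.end):
                if not any(e.contains_point(edge) for e in self.exons):
                    raise ValueError(
                        f"CDS edge {edge} not inside any exon of {self.transcript_id}"
                    )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom,
            self.exons[0].start,
            self.exons[-1].end,
            self.exons[0].strand,
        )

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass(frozen=True)
class GeneModel:
    """A gene: its genomic span and all annotated transcript isoforms."""

    symbol: str
    span: GenomicInterval
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise ValueError(f"gene {self.symbol} has no transcripts")
        for t in self.transcripts:
            for e in t.exons:
                if not self.span.contains(e):
                    raise ValueError(
                        f"exon {e} of {t.transcript_id} outside gene span of {self.symbol}"
                    )

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def is_autosomal(self) -> bool:
        return self.span.chrom in AUTOSOMES

    def transcripts_of(self, species: str) -> tuple[TranscriptModel, ...]:
        return tuple(t for t in self.transcripts if t.species == species)

    @property
    def principal_transcript(self) -> Optional[TranscriptModel]:
        for t in self.transcripts:
            if t.principal:
                return t
        return None


@dataclass(frozen=True)
class VariationRecord:
    """A typed human-specific variation.

    hCONDELs (and point-anchored deletions) carry a single human anchor
    coordinate plus the length of the ancestral sequence lost in the human
    lineage, so ``locus`` may be a point while ``length_bp`` is large.
    ``span_matches_length`` reports whether a ranged record's printed length
    agrees with its inclusive span; records where it does not are kept as
    printed and flagged convention-ambiguous rather than silently altered.
    """

    var_id: str
    vtype: VariationType
    locus: GenomicInterval
    length_bp: int
    source: str = ""
    also_str: bool = False
    validated: str = "pending"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.var_id}: length_bp must be >= 1")
        if self.validated not in VALIDATION_STATES:
            raise ValueError(f"{self.var_id}: bad validation state {self.validated!r}")
        if self.also_str and self.vtype is not VariationType.INSERTION:
            raise ValueError(f"{self.var_id}: also_str applies to insertions only")

    @property
    def span_matches_length(self) -> bool:
        """Inclusive span length equals the stated length (vacuous for points)."""
        if self.locus.is_point:
            return True
        return self.locus.length == self.length_bp

    def admissible_to_pond(self) -> bool:
        """Type-specific size rule: indels must exceed 50 bp, HSDs 1 kb."""
        if self.vtype in (VariationType.INSERTION, VariationType.DELETION):
            return self.length_bp > INDEL_MIN_BP
        if self.vtype is VariationType.HSD:
            return self.length_bp > HSD_MIN_BP
        return True


@dataclass(frozen=True)
class BaitGene:
    """A non-redundant GWAS-implicated gene with its study provenance."""

    symbol: str
    span: GenomicInterval
    sources: frozenset[str]
    lead_snps: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "lead_snps", tuple(self.lead_snps))
        if not self.sources:
            raise ValueError(f"bait gene {self.symbol} has no source studies")


@dataclass(frozen=True)
class PreyHit:
    """A gene x variation intersection.

    ``within_gene`` records whether the exact 1-based spans intersect; a
    kilobase-bucket hit can be true while the variation lies up to
    bucket_bp - 1 bases outside the gene.
    """

    gene_symbol: str
    var_id: str
    method: str  # "kb_bucket" | "exact"
    within_gene: bool

    def __post_init__(self) -> None:
        if self.method not in ("kb_bucket", "exact"):
            raise ValueError(f"unknown overlap method {self.method!r}")


class PositionalClass(enum.Enum):
    """Where a variation falls relative to gene structure, most consequential first."""

    CDS_EXON = "CDS_EXON"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    NONCODING_EXON = "NONCODING_EXON"
    INTRON = "INTRON"
    FLANK = "FLANK"

    def __str__(self) -> str:
        return self.value


#: Precedence used to pick the reported class across isoforms.
PCLASS_PRECEDENCE = {
    PositionalClass.CDS_EXON: 5,
    PositionalClass.UTR5: 4,
    PositionalClass.UTR3: 4,
    PositionalClass.NONCODING_EXON: 3,
    PositionalClass.INTRON: 2,
    PositionalClass.FLANK: 1,
}

EXONIC_CLASSES = frozenset(
    {
        PositionalClass.CDS_EXON,
        PositionalClass.UTR5,
        PositionalClass.UTR3,
        PositionalClass.NONCODING_EXON,
    }
)


@dataclass(frozen=True)
class PositionalCall:
    """The resolved positional class of one variation in one gene."""

    gene_symbol: str
    var_id: str
    pclass: PositionalClass
    nearest_exon_distance: int = 0
    isoform_id: str = ""

    def __post_init__(self) -> None:
        if self.nearest_exon_distance < 0:
            raise ValueError("nearest_exon_distance must be >= 0")


class HiegCategory(enum.Enum):
    """Admission categories for human intelligence evolution genes."""

    EXON_GAIN_LOSS = "exon_gain_loss"
    HCONDEL = "hCONDEL"
    HSD = "HSD"
    INDEL = "indel"
    STR = "STR"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class HiegRecord:
    """A selected HIEG candidate with its variations and admitting categories."""

    gene_symbol: str
    variations: tuple[str, ...]
    categories: frozenset[HiegCategory]
    admit_rule: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "variations", tuple(self.variations))
        object.__setattr__(self, "categories", frozenset(self.categories))
        if not self.categories:
            raise ValueError(f"HIEG {self.gene_symbol} has no categories")


def genes_by_symbol(genes: Sequence[GeneModel]) -> dict[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for g in genes:
        if g.symbol in out:
            raise ValueError(f"duplicate gene symbol {g.symbol}")
        out[g.symbol] = g
    return out
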