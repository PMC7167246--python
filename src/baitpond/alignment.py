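"""Local-alignment confirmation of candidate human-specific variations.

Each candidate is checked against the great-ape genomes at desk scale:
the variant plus flanking human sequence is compared with the orthologous
ape sequence by Smith-Waterman local alignment (match +1, mismatch -2,
gap open -5, gap extend -2 — BLASTn-like scoring).

A variation is confirmed human-specific when every supplied ape species
shows the expected ancestral state:

* insertion-type (insertion, STR expansion, exon gain): the inserted
  segment must be *absent* from the ape sequence — no local alignment at
  >= ``min_identity`` identity covering >= ``min_coverage`` of the segment;
* deletion-type (deletion, hCONDEL, STR contraction, exon loss): the
  ancestral segment must be *present* in the ape sequence and absent from
  the human sequence.

Candidates failing in any species are rejected, with the failing species
named — the desk-scale analogue of removing variations undetectable by a
local BLAST against the ape assemblies.  Identity thresholds replace
E-values, which are database-size dependent and meaningless without a
genome-scale database.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional

from Bio import Align

from .records import VariationType

DNA_ALPHABET = frozenset("ACGTN")

#: Fraction of the query segment that must be covered for a "found" call.
DEFAULT_MIN_COVERAGE = 0.8
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_FLANK_BP = 500

_INSERTION_LIKE = frozenset(
    {VariationType.INSERTION, VariationType.STR_EXPANSION, VariationType.EXON_GAIN}
)
_DELETION_LIKE = frozenset(
    {
        VariationType.DELETION,
        VariationType.HCONDEL,
        VariationType.STR_CONTRACTION,
        VariationType.EXON_LOSS,
    }
)


class InsufficientContextError(ValueError):
    """An ape sequence is too short to provide alignment context."""


@lru_cache(maxsize=None)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-2,
        open_gap_score=-5,
        extend_gap_score=-2,
    )
    return aligner


@dataclass(frozen=True)
class LocalAlignment:
    """Identity and query coverage of the best local alignment."""

    score: float
    identity: float  # matches / aligned columns (gaps included)
    coverage: float  # aligned query positions / query length


def align_local(query: str, target: str) -> LocalAlignment:
    """Best Smith-Waterman local alignment of *query* against *target*."""
    if not query or not target:
        return LocalAlignment(score=0.0, identity=0.0, coverage=0.0)
    aln = _aligner().align(query.upper(), target.upper())
    if len(aln) == 0:  # pragma: no cover - local alignment always yields >= empty
        return LocalAlignment(score=0.0, identity=0.0, coverage=0.0)
    best = aln[0]
    counts = best.counts()
    columns = counts.aligned + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    q_aligned = sum(int(b - a) for a, b in best.aligned[0])
    return LocalAlignment(
        score=float(best.score),
        identity=identity,
        coverage=q_aligned / len(query),
    )


def segment_found(
    segment: str,
    target: str,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> bool:
    """Is *segment* detectably present in *target*?

    True iff the best local alignment reaches *min_identity* identity while
    covering at least *min_coverage* of the segment.
    """
    hit = align_local(segment, target)
    return hit.identity >= min_identity and hit.coverage >= min_coverage


@dataclass(frozen=True)
class ValidationCase:
    """One candidate variation with its human sequence context and ape orthologs.

    For insertion-type candidates, ``human_seq`` carries the inserted
    segment at ``insert_offset`` (0-based) with length ``insert_length``.
    For deletion-type candidates the lost ancestral segment is supplied
    separately as ``ancestral_seq`` (the human footprint is a joint point).
    """

    var_id: str
    vtype: VariationType
    human_seq: str
    ape_seqs: Mapping[str, str]
    flank_bp: int = DEFAULT_FLANK_BP
    insert_offset: Optional[int] = None
    insert_length: Optional[int] = None
    ancestral_seq: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "human_seq", self.human_seq.upper())
        object.__setattr__(
            self, "ape_seqs", {sp: s.upper() for sp, s in self.ape_seqs.items()}
        )
        if self.flank_bp < 1:
            raise ValueError("flank_bp must be >= 1")
        for label, seq in [("human", self.human_seq), *self.ape_seqs.items()]:
            if set(seq) - DNA_ALPHABET:
                raise ValueError(f"{self.var_id}: non-ACGTN characters in {label} sequence")
        if self.vtype in _INSERTION_LIKE:
            if self.insert_offset is None or self.insert_length is None:
                raise ValueError(
                    f"{self.var_id}: insertion-type case needs insert_offset/insert_length"
                )
            if self.insert_offset + self.insert_length > len(self.human_seq):
                raise ValueError(f"{self.var_id}: inserted segment outside human_seq")
        elif self.vtype in _DELETION_LIKE:
            if not self.ancestral_seq:
                raise ValueError(
                    f"{self.var_id}: deletion-type case needs the ancestral segment"
                )
            object.__setattr__(self, "ancestral_seq", self.ancestral_seq.upper())
        else:
            raise ValueError(f"{self.var_id}: {self.vtype.value} is not alignable")

    @property
    def inserted_segment(self) -> str:
        assert self.insert_offset is not None and self.insert_length is not None
        return self.human_seq[self.insert_offset : self.insert_offset + self.insert_length]


@dataclass(frozen=True)
class ValidationVerdict:
    """Per-species evidence and the overall validated/rejected call."""

    var_id: str
    status: str  # "validated" | "rejected"
    failing_species: tuple[str, ...] = ()
    evidence: Mapping[str, str] = field(default_factory=dict)
    skipped_species: tuple[str, ...] = ()


def validate_variation(
    case: ValidationCase,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> ValidationVerdict:
    """Confirm or reject one candidate against every supplied ape species.

    Validated iff every species with sequence shows the human-specific
    state; species with missing sequence are skipped with a warning entry,
    and an ape sequence shorter than ``flank_bp`` raises
    :class:`InsufficientContextError`.
    """
    failing: list[str] = []
    skipped: list[str] = []
    evidence: dict[str, str] = {}
    for species in sorted(case.ape_seqs):
        ape = case.ape_seqs[species]
        if not ape:
            skipped.append(species)
            evidence[species] = "no sequence; skipped"
            continue
        if len(ape) < case.flank_bp:
            raise InsufficientContextError(
                f"{case.var_id}: {species} sequence ({len(ape)} bp) shorter than "
                f"flank_bp ({case.flank_bp})"
            )
        if case.vtype in _INSERTION_LIKE:
            present = segment_found(
                case.inserted_segment, ape, min_identity, min_coverage
            )
            if present:
                failing.append(species)
                evidence[species] = "inserted segment detected in ape"
            else:
                evidence[species] = "inserted segment absent from ape"
        else:
            assert case.ancestral_seq is not None
            in_ape = segment_found(case.ancestral_seq, ape, min_identity, min_coverage)
            in_human = segment_found(
                case.ancestral_seq, case.human_seq, min_identity, min_coverage
            )
            if in_ape and not in_human:
                evidence[species] = "ancestral segment present in ape, absent in human"
            else:
                failing.append(species)
                evidence[species] = (
                    "ancestral segment not found in ape"
                    if not in_ape
                    else "ancestral segment still present in human"
                )
    tested = [sp for sp in case.ape_seqs if sp not in skipped]
    status = "validated" if tested and not failing else "rejected"
    return ValidationVerdict(
        var_id=case.var_id,
        status=status,
        failing_species=tuple(failing),
        evidence=evidence,
        skipped_species=tuple(skipped),
    )


# ---------------------------------------------------------------------------
# FASTA case serialisation: one file per case, record ids "<var_id>|<role>",
# the human record's description carrying the case parameters.


def write_case_fasta(case: ValidationCase, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    desc = f"vtype={case.vtype.value} flank_bp={case.flank_bp}"
    if case.vtype in _INSERTION_LIKE:
        desc += f" insert_offset={case.insert_offset} insert_length={case.insert_length}"
    records = [
        SeqRecord(Seq(case.human_seq), id=f"{case.var_id}|human", description=desc)
    ]
    if case.ancestral_seq:
        records.append(
            SeqRecord(Seq(case.ancestral_seq), id=f"{case.var_id}|ancestral", description="")
        )
    for species, seq in case.ape_seqs.items():
        records.append(SeqRecord(Seq(seq), id=f"{case.var_id}|{species}", description=""))
    seqio_write(records, str(path), "fasta")


def read_case_fasta(path) -> ValidationCase:
    from Bio import SeqIO

    human_seq = ancestral = None
    params: dict[str, str] = {}
    var_id = None
    ape_seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, _, role = rec.id.partition("|")
        var_id = var_id or rid
        if role == "human":
            human_seq = str(rec.seq)
            for token in rec.description.split()[1:]:
                if "=" in token:
                    k, v = token.split("=", 1)
                    params[k] = v
        elif role == "ancestral":
            ancestral = str(rec.seq)
        else:
            ape_seqs[role] = str(rec.seq)
    if var_id is None or human_seq is None:
        raise ValueError(f"{path}: no human record found")
    vtype = VariationType(params["vtype"])
    return ValidationCase(
        var_id=var_id,
        vtype=vtype,
        human_seq=human_seq,
        ape_seqs=ape_seqs,
        flank_bp=int(params.get("flank_bp", DEFAULT_FLANK_BP)),
        insert_offset=(
            int(params["insert_offset"]) if "insert_offset" in params else None
        ),
        insert_length=(
            int(params["insert_length"]) if "insert_length" in params else None
        ),
        ancestral_seq=ancestral,
    )
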