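"""Genomic coordinate primitives.

Everything in the pipeline is expressed in 1-based inclusive coordinates,
the convention of Ensembl gene annotation and of the published variation
tables this package consumes.  BED input (0-based half-open) is converted
on read; see :mod:`baitpond.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AUTOSOMES = frozenset(str(i) for i in range(1, 23))
SEX_CHROMOSOMES = frozenset({"X", "Y"})

STRANDS = frozenset({"+", "-", "."})


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and surrounding whitespace from a chromosome label."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on a chromosome.

    ``start == end`` denotes a point anchor (used for lead SNPs and for
    hCONDEL records, whose human footprint is a single coordinate).
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        """Span length in bases under the inclusive convention."""
        return self.end - self.start + 1

    @property
    def is_point(self) -> bool:
        return self.start == self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share at least one base (same chromosome)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this span."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bases between two spans; 0 if they overlap, 1 if adjacent.

        Defined on the same chromosome only.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap_to is undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end < other.start:
            return other.start - self.end
        return self.start - other.end

    def bucket_range(self, bucket_bp: int) -> tuple[int, int]:
        """Kilobase-bucket span: floor-divide both endpoints by *bucket_bp*."""
        if bucket_bp < 1:
            raise ValueError("bucket_bp must be >= 1")
        return self.start // bucket_bp, self.end // bucket_bp

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort autosomes numerically, then other labels lexicographically."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (int(c), "")
    return (1000, c)
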