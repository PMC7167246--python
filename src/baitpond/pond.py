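"""Assembly of the human-specific variation pond.

The pond pools typed structural variations between the human genome and
the great-ape assemblies: STR contractions/expansions, insertions and
deletions over 50 bp, hCONDELs, human-specific segmental duplications
(HSDs, >1 kb at >90% similarity), inversions, and exon gain/loss events.
Size filters apply only where the source definitions impose them (indels
and HSDs); inversions, hCONDELs and STRs enter unfiltered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .records import HSD_MIN_BP, INDEL_MIN_BP, VariationRecord, VariationType

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariationPond:
    """The pooled, size-filtered variation set with per-type tallies."""

    records: tuple[VariationRecord, ...]
    rejected: tuple[VariationRecord, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "rejected", tuple(self.rejected))
        for r in self.records:
            if not r.admissible_to_pond():
                raise ValueError(
                    f"record {r.var_id} violates the {r.vtype.value} size rule"
                )

    @property
    def counts_by_type(self) -> dict[VariationType, int]:
        counts = {vt: 0 for vt in VariationType}
        for r in self.records:
            counts[r.vtype] += 1
        return counts

    def of_type(self, vtype: VariationType) -> list[VariationRecord]:
        return [r for r in self.records if r.vtype is vtype]

    def by_id(self) -> dict[str, VariationRecord]:
        return {r.var_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def build_pond(
    sources: Mapping[VariationType | str, Sequence[VariationRecord]]
    | Iterable[tuple[VariationType | str, Sequence[VariationRecord]]],
) -> VariationPond:
    """Pool per-type source call sets into a pond, applying size rules.

    *sources* maps a variation type tag to the records from that call set;
    records whose own ``vtype`` disagrees with their tag are a
    configuration error, as is an unrecognised tag.  Indels of 50 bp or
    less and HSDs of 1 kb or less are rejected (and logged), mirroring the
    pond's stated admission rules.
    """
    from .records import parse_vtype

    items = sources.items() if isinstance(sources, Mapping) else sources
    admitted: list[VariationRecord] = []
    rejected: list[VariationRecord] = []
    for tag, records in items:
        vtype = tag if isinstance(tag, VariationType) else parse_vtype(str(tag))
        for r in records:
            if r.vtype is not vtype:
                raise ValueError(
                    f"record {r.var_id} is {r.vtype.value} but tagged {vtype.value}"
                )
            if r.admissible_to_pond():
                admitted.append(r)
            else:
                rejected.append(r)
                limit = INDEL_MIN_BP if r.vtype is not VariationType.HSD else HSD_MIN_BP
                logger.info(
                    "rejected %s (%s, %d bp <= %d bp)",
                    r.var_id, r.vtype.value, r.length_bp, limit,
                )
    return VariationPond(records=tuple(admitted), rejected=tuple(rejected))


def filter_hsd_large(pond: VariationPond, min_len: int = 5000) -> list[VariationRecord]:
    """HSD records longer than *min_len* bp (default: the >5 kb large-HSD set)."""
    return [
        r
        for r in pond.records
        if r.vtype is VariationType.HSD and r.length_bp > min_len
    ]
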