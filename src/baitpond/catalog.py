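"""The packaged HIEG catalogue.

A transcription of the published table of human intelligence evolution
gene candidates: 40 genes on the autosomes carrying 47 typed human-specific
variations (several genes carry more than one).  Positions are 1-based
inclusive; hCONDELs and the one point-anchored deletion are given as a
single human anchor coordinate with the length of the lost ancestral
sequence.  Each variation also carries the positional class reported for
it (all hCONDELs are intronic; the admitted indels and STRs are exonic).

One row is deliberately inconsistent: the PCCB exon gain is printed as
span 136326325-136326385 with length 60, which is 61 bp inclusive.  The
record is stored as printed and exposed via
``convention_ambiguous_ids()`` rather than silently corrected.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .intervals import GenomicInterval
from .records import (
    PositionalCall,
    PositionalClass,
    VariationRecord,
    parse_vtype,
)

_CATALOG_RESOURCE = "hieg_catalog.tsv"


@dataclass(frozen=True)
class Catalog:
    """Gene spans, variation records and positional calls of the catalogue."""

    gene_spans: dict[str, GenomicInterval]
    variations: tuple[VariationRecord, ...]
    calls: tuple[PositionalCall, ...]
    snps: dict[str, tuple[str, ...]]  # gene -> related SNP ids
    disorders: dict[str, str]

    @property
    def gene_symbols(self) -> list[str]:
        return sorted(self.gene_spans)

    def variations_of(self, gene: str) -> list[VariationRecord]:
        prefix = f"{gene}:"
        return [v for v in self.variations if v.var_id.startswith(prefix)]

    def convention_ambiguous_ids(self) -> list[str]:
        """Ranged records whose printed length disagrees with the inclusive span."""
        return [v.var_id for v in self.variations if not v.span_matches_length]


def _catalog_frame() -> pd.DataFrame:
    ref = importlib.resources.files("baitpond.data").joinpath(_CATALOG_RESOURCE)
    with ref.open("rb") as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


def load_catalog() -> Catalog:
    """Load the packaged catalogue into typed records."""
    df = _catalog_frame()
    gene_spans: dict[str, GenomicInterval] = {}
    variations: list[VariationRecord] = []
    calls: list[PositionalCall] = []
    snps: dict[str, list[str]] = {}
    disorders: dict[str, str] = {}
    for row in df.to_dict("records"):
        gene = row["gene"]
        gene_spans.setdefault(
            gene,
            GenomicInterval(row["chrom"], int(row["gene_start"]), int(row["gene_end"])),
        )
        vtype = parse_vtype(row["vtype"])
        var_id = f"{gene}:{vtype.value}:{row['var_start']}"
        rec = VariationRecord(
            var_id=var_id,
            vtype=vtype,
            locus=GenomicInterval(row["chrom"], int(row["var_start"]), int(row["var_end"])),
            length_bp=int(row["length"]),
            source="catalog",
            also_str=str(row["also_str"]) == "1",
        )
        variations.append(rec)
        calls.append(
            PositionalCall(
                gene_symbol=gene,
                var_id=var_id,
                pclass=PositionalClass(row["pclass"]),
                nearest_exon_distance=0,
            )
        )
        snp = row.get("snp")
        if isinstance(snp, str) and snp:
            snps.setdefault(gene, [])
            if snp not in snps[gene]:
                snps[gene].append(snp)
        disorder = row.get("disorder")
        if isinstance(disorder, str) and disorder and disorder == disorder:
            disorders[gene] = disorder
    return Catalog(
        gene_spans=gene_spans,
        variations=tuple(variations),
        calls=tuple(calls),
        snps={g: tuple(v) for g, v in snps.items()},
        disorders=disorders,
    )
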