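"""Bait-gene integration: non-redundant GWAS gene set with study provenance.

Lead SNPs from several intelligence GWAS each carry a nearest-gene
annotation (taken as given from the source studies; proximity is not
recomputed here).  Integration unions the studies per gene, removes
redundancy, and drops X/Y-linked genes, whose association signal is
unreliable where cohorts did not impute the X chromosome.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .intervals import chrom_sort_key
from .records import BaitGene, GeneModel, LeadSnp

logger = logging.getLogger(__name__)


def count_loci(snps: Sequence[LeadSnp]) -> int:
    """Number of distinct association loci among the lead SNPs.

    SNPs sharing a locus identifier belong to one locus; a SNP without one
    is its own locus.
    """
    return len({s.effective_locus_id for s in snps})


def integrate_bait_genes(
    snps: Sequence[LeadSnp],
    genes: Sequence[GeneModel] | Mapping[str, GeneModel],
) -> tuple[list[BaitGene], list[str]]:
    """Integrate lead SNPs into one bait gene per unique nearest-gene symbol.

    Returns ``(bait, unresolved)`` where *unresolved* lists nearest-gene
    symbols that could not be matched to a gene model (reported, never
    silently dropped).  Lead SNPs with no nearest gene are excluded with a
    warning.  Output order is deterministic: by chromosome, then start.
    """
    if not isinstance(genes, Mapping):
        genes = {g.symbol: g for g in genes}
    by_symbol: dict[str, dict] = {}
    unresolved: list[str] = []
    for snp in snps:
        if not snp.nearest_gene:
            logger.warning("lead SNP %s has no nearest gene; excluded", snp.rsid)
            continue
        if snp.nearest_gene not in genes:
            unresolved.append(snp.nearest_gene)
            continue
        slot = by_symbol.setdefault(snp.nearest_gene, {"sources": set(), "snps": []})
        slot["sources"].add(snp.study_id)
        slot["snps"].append(snp.rsid)
    bait = [
        BaitGene(
            symbol=symbol,
            span=genes[symbol].span,
            sources=frozenset(slot["sources"]),
            lead_snps=tuple(sorted(set(slot["snps"]))),
        )
        for symbol, slot in by_symbol.items()
    ]
    bait.sort(key=lambda b: (chrom_sort_key(b.span.chrom), b.span.start, b.symbol))
    return bait, sorted(set(unresolved))


def exclude_sex_chromosomes(bait: Sequence[BaitGene]) -> list[BaitGene]:
    """Drop bait genes on X or Y, keeping only autosomal genes."""
    kept = [b for b in bait if b.span.chrom in {str(i) for i in range(1, 23)}]
    removed = len(bait) - len(kept)
    if removed:
        logger.info("excluded %d sex-chromosome bait gene(s)", removed)
    return kept
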