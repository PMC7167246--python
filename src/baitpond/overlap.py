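"""Bait x pond intersection: the kilobase-bucket method and its exact oracle.

The operative intersection divides every coordinate by a 1-kb bucket and
calls a hit when a variation's bucket range meets a gene's bucket range on
the same chromosome.  This admits variations up to bucket_bp - 1 bases
outside the gene span, so each hit also records ``within_gene`` — whether
the exact 1-based spans intersect — letting downstream stages distinguish
flank hits.  A brute-force exact-interval oracle is provided for
verification; exact hits are always a subset of bucket hits.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .intervals import chrom_sort_key
from .pond import VariationPond
from .records import BaitGene, PreyHit, VariationRecord, VariationType


def _records(pond: VariationPond | Sequence[VariationRecord]) -> tuple[VariationRecord, ...]:
    return pond.records if isinstance(pond, VariationPond) else tuple(pond)


def _sorted_hits(hits: dict[tuple[str, str], bool], method: str,
                 gene_order: Mapping[str, tuple], var_order: Mapping[str, tuple]) -> list[PreyHit]:
    keys = sorted(hits, key=lambda k: (gene_order[k[0]], var_order[k[1]]))
    return [
        PreyHit(gene_symbol=g, var_id=v, method=method, within_gene=hits[(g, v)])
        for g, v in keys
    ]


def _orders(bait: Sequence[BaitGene], records: Sequence[VariationRecord]):
    gene_order = {
        b.symbol: (chrom_sort_key(b.span.chrom), b.span.start, b.symbol) for b in bait
    }
    var_order = {
        r.var_id: (chrom_sort_key(r.locus.chrom), r.locus.start, r.var_id)
        for r in records
    }
    return gene_order, var_order


def kb_bucket_overlap(
    pond: VariationPond | Sequence[VariationRecord],
    bait: Sequence[BaitGene],
    bucket_bp: int = 1000,
) -> list[PreyHit]:
    """Intersect variations with bait genes on floor(coordinate / bucket_bp) buckets.

    A hit is emitted iff the chromosomes match and the bucket ranges of the
    variation span and the gene span intersect.  Point records (hCONDEL
    anchors, point-anchored deletions) use start == end.  Output order is
    deterministic (gene position, then variation position) and independent
    of input ordering.
    """
    if bucket_bp < 1:
        raise ValueError("bucket_bp must be >= 1")
    records = _records(pond)
    gene_buckets: dict[str, dict[int, list[BaitGene]]] = defaultdict(lambda: defaultdict(list))
    gene_bucket_span: dict[str, tuple[int, int]] = {}
    for b in bait:
        lo, hi = b.span.bucket_range(bucket_bp)
        gene_bucket_span[b.symbol] = (lo, hi)
        for k in range(lo, hi + 1):
            gene_buckets[b.span.chrom][k].append(b)
    hits: dict[tuple[str, str], bool] = {}
    for r in records:
        lo, hi = r.locus.bucket_range(bucket_bp)
        chrom_map = gene_buckets.get(r.locus.chrom)
        if not chrom_map:
            continue
        for k in range(lo, hi + 1):
            for b in chrom_map.get(k, ()):
                key = (b.symbol, r.var_id)
                if key not in hits:
                    hits[key] = r.locus.overlaps(b.span)
    gene_order, var_order = _orders(bait, records)
    return _sorted_hits(hits, "kb_bucket", gene_order, var_order)


def exact_overlap_oracle(
    pond: VariationPond | Sequence[VariationRecord],
    bait: Sequence[BaitGene],
) -> list[PreyHit]:
    """Brute-force 1-based inclusive interval intersection, the verification oracle."""
    records = _records(pond)
    by_chrom: dict[str, list[VariationRecord]] = defaultdict(list)
    for r in records:
        by_chrom[r.locus.chrom].append(r)
    hits: dict[tuple[str, str], bool] = {}
    for b in bait:
        for r in by_chrom.get(b.span.chrom, ()):
            if r.locus.overlaps(b.span):
                hits[(b.symbol, r.var_id)] = True
    gene_order, var_order = _orders(bait, records)
    return _sorted_hits(hits, "exact", gene_order, var_order)


@dataclass(frozen=True)
class PreySummary:
    """Distinct-gene and variation tallies over a set of prey hits.

    A gene hit by several variations counts once overall and once in each
    type's tally it participates in.
    """

    n_genes: int
    n_variations: int
    genes_by_type: dict[VariationType, int] = field(default_factory=dict)
    variations_by_type: dict[VariationType, int] = field(default_factory=dict)


def prey_summary(
    hits: Sequence[PreyHit],
    pond: VariationPond | Sequence[VariationRecord] | Mapping[str, VariationRecord],
) -> PreySummary:
    """Tally distinct prey genes and variations, overall and per variation type."""
    if isinstance(pond, Mapping):
        by_id = dict(pond)
    else:
        by_id = {r.var_id: r for r in _records(pond)}
    genes: set[str] = set()
    variations: set[str] = set()
    genes_by_type: dict[VariationType, set[str]] = defaultdict(set)
    vars_by_type: dict[VariationType, set[str]] = defaultdict(set)
    for h in hits:
        if h.var_id not in by_id:
            raise KeyError(f"prey hit references unknown variation {h.var_id!r}")
        vt = by_id[h.var_id].vtype
        genes.add(h.gene_symbol)
        variations.add(h.var_id)
        genes_by_type[vt].add(h.gene_symbol)
        vars_by_type[vt].add(h.var_id)
    return PreySummary(
        n_genes=len(genes),
        n_variations=len(variations),
        genes_by_type={vt: len(s) for vt, s in genes_by_type.items()},
        variations_by_type={vt: len(s) for vt, s in vars_by_type.items()},
    )
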