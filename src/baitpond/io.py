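"""Readers and writers for the pipeline's tabular and sequence formats.

TSV schemas have fixed headers; every read enforces the domain invariants
and reports offending rows by line number.  BED input is 0-based half-open
and is converted to the internal 1-based inclusive convention on read.
GFF3 parsing goes through gffutils; FASTA through Bio.SeqIO.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval, normalize_chrom
from .records import (
    BaitGene,
    GeneModel,
    HiegCategory,
    HiegRecord,
    LeadSnp,
    PositionalCall,
    PositionalClass,
    PreyHit,
    TranscriptModel,
    VariationRecord,
    parse_vtype,
)


class SchemaError(ValueError):
    """The file header does not match the requested table schema."""


class TableParseError(ValueError):
    """One or more rows violated the schema's invariants."""


SCHEMAS: dict[str, list[str]] = {
    "lead_snps": ["rsid", "chrom", "pos", "study", "p", "nearest_gene", "locus_id"],
    "bait": ["symbol", "chrom", "start", "end", "sources", "lead_snps"],
    "pond": [
        "var_id",
        "chrom",
        "start",
        "end",
        "type",
        "length",
        "source",
        "also_str",
        "validated",
    ],
    "prey": ["gene_symbol", "var_id", "method", "within_gene"],
    "calls": ["gene_symbol", "var_id", "pclass", "nearest_exon_distance", "isoform_id"],
    "hieg": ["gene_symbol", "variations", "categories", "admit_rule"],
}

_OPTIONAL_COLUMNS = {"lead_snps": {"p", "locus_id"}, "pond": {"also_str", "validated"}}


def _opt(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return str(value)


def _row_lead_snp(row: dict) -> LeadSnp:
    p = _opt(row.get("p"))
    return LeadSnp(
        rsid=str(row["rsid"]),
        locus=GenomicInterval(str(row["chrom"]), int(row["pos"]), int(row["pos"])),
        study_id=str(row["study"]),
        nearest_gene=_opt(row.get("nearest_gene")) or "",
        p_value=float(p) if p is not None else None,
        locus_id=_opt(row.get("locus_id")),
    )


def _row_bait(row: dict) -> BaitGene:
    sources = [s for s in str(row["sources"]).split(",") if s]
    snps = _opt(row.get("lead_snps"))
    return BaitGene(
        symbol=str(row["symbol"]),
        span=GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
        sources=frozenset(sources),
        lead_snps=tuple(snps.split(",")) if snps else (),
    )


def _row_pond(row: dict) -> VariationRecord:
    return VariationRecord(
        var_id=str(row["var_id"]),
        vtype=parse_vtype(str(row["type"])),
        locus=GenomicInterval(str(row["chrom"]), int(row["start"]), int(row["end"])),
        length_bp=int(row["length"]),
        source=_opt(row.get("source")) or "",
        also_str=str(row.get("also_str", "0")).strip() in ("1", "True", "true"),
        validated=_opt(row.get("validated")) or "pending",
    )


def _row_prey(row: dict) -> PreyHit:
    return PreyHit(
        gene_symbol=str(row["gene_symbol"]),
        var_id=str(row["var_id"]),
        method=str(row["method"]),
        within_gene=str(row["within_gene"]).strip() in ("1", "True", "true"),
    )


def _row_call(row: dict) -> PositionalCall:
    return PositionalCall(
        gene_symbol=str(row["gene_symbol"]),
        var_id=str(row["var_id"]),
        pclass=PositionalClass(str(row["pclass"])),
        nearest_exon_distance=int(row["nearest_exon_distance"]),
        isoform_id=_opt(row.get("isoform_id")) or "",
    )


def _row_hieg(row: dict) -> HiegRecord:
    return HiegRecord(
        gene_symbol=str(row["gene_symbol"]),
        variations=tuple(v for v in str(row["variations"]).split(",") if v),
        categories=frozenset(
            HiegCategory(c) for c in str(row["categories"]).split(",") if c
        ),
        admit_rule=_opt(row.get("admit_rule")) or "",
    )


_ROW_BUILDERS = {
    "lead_snps": _row_lead_snp,
    "bait": _row_bait,
    "pond": _row_pond,
    "prey": _row_prey,
    "calls": _row_call,
    "hieg": _row_hieg,
}


def read_table(path: str | os.PathLike, schema: str) -> list:
    """Read a TSV of the named schema into typed, invariant-checked records.

    Raises :class:`SchemaError` if required columns are missing and
    :class:`TableParseError` naming every offending row otherwise.
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = set(SCHEMAS[schema]) - _OPTIONAL_COLUMNS.get(schema, set())
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {sorted(missing)} for schema {schema!r}"
        )
    build = _ROW_BUILDERS[schema]
    records, errors = [], []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(build(row))
        except (ValueError, KeyError) as exc:  # line 1 is the header
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        raise TableParseError(f"{path}: " + "; ".join(errors))
    return records


def _fmt_float(x: Optional[float]) -> str:
    return "" if x is None else repr(x)


def _record_row(record) -> dict:
    if isinstance(record, LeadSnp):
        return {
            "rsid": record.rsid,
            "chrom": record.locus.chrom,
            "pos": record.locus.start,
            "study": record.study_id,
            "p": _fmt_float(record.p_value),
            "nearest_gene": record.nearest_gene,
            "locus_id": record.locus_id or "",
        }
    if isinstance(record, BaitGene):
        return {
            "symbol": record.symbol,
            "chrom": record.span.chrom,
            "start": record.span.start,
            "end": record.span.end,
            "sources": ",".join(sorted(record.sources)),
            "lead_snps": ",".join(record.lead_snps),
        }
    if isinstance(record, VariationRecord):
        return {
            "var_id": record.var_id,
            "chrom": record.locus.chrom,
            "start": record.locus.start,
            "end": record.locus.end,
            "type": record.vtype.value,
            "length": record.length_bp,
            "source": record.source,
            "also_str": int(record.also_str),
            "validated": record.validated,
        }
    if isinstance(record, PreyHit):
        return {
            "gene_symbol": record.gene_symbol,
            "var_id": record.var_id,
            "method": record.method,
            "within_gene": int(record.within_gene),
        }
    if isinstance(record, PositionalCall):
        return {
            "gene_symbol": record.gene_symbol,
            "var_id": record.var_id,
            "pclass": record.pclass.value,
            "nearest_exon_distance": record.nearest_exon_distance,
            "isoform_id": record.isoform_id,
        }
    if isinstance(record, HiegRecord):
        return {
            "gene_symbol": record.gene_symbol,
            "variations": ",".join(record.variations),
            "categories": ",".join(sorted(c.value for c in record.categories)),
            "admit_rule": record.admit_rule,
        }
    raise TypeError(f"cannot serialise record of type {type(record).__name__}")


_SCHEMA_OF_TYPE = {
    LeadSnp: "lead_snps",
    BaitGene: "bait",
    VariationRecord: "pond",
    PreyHit: "prey",
    PositionalCall: "calls",
    HiegRecord: "hieg",
}


def write_table(
    records: Sequence, path: str | os.PathLike, schema: Optional[str] = None
) -> None:
    """Write homogeneous records as a TSV; an empty list needs an explicit schema."""
    if records:
        types = {type(r) for r in records}
        if len(types) > 1:
            raise TypeError(f"records not homogeneous: {sorted(t.__name__ for t in types)}")
        inferred = _SCHEMA_OF_TYPE.get(types.pop())
        if inferred is None:
            raise TypeError("unsupported record type")
        if schema is not None and schema != inferred:
            raise ValueError(f"records are {inferred!r}, not {schema!r}")
        schema = inferred
    elif schema is None:
        raise ValueError("schema must be given for an empty record list")
    columns = SCHEMAS[schema]
    df = pd.DataFrame([_record_row(r) for r in records], columns=columns)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED


def read_bed_variations(
    path: str | os.PathLike, vtype_label: str, source: str = ""
) -> list[VariationRecord]:
    """Read a 3+ column BED file as variation records of one type.

    BED is 0-based half-open: a line ``chr3 48968204 48968380`` becomes the
    1-based inclusive span 48968205-48968380 (length 176).  Column 4, when
    present, is taken as the record id.
    """
    vtype = parse_vtype(vtype_label)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TableParseError(f"{path}: line {i + 1}: fewer than 3 BED columns")
            try:
                chrom = normalize_chrom(parts[0])
                start = int(parts[1]) + 1
                end = int(parts[2])
            except ValueError as exc:
                raise TableParseError(f"{path}: line {i + 1}: {exc}") from exc
            var_id = parts[3] if len(parts) > 3 and parts[3] not in (".", "") else (
                f"{vtype.value}:{chrom}:{start}"
            )
            records.append(
                VariationRecord(
                    var_id=var_id,
                    vtype=vtype,
                    locus=GenomicInterval(chrom, start, end),
                    length_bp=end - start + 1,
                    source=source,
                )
            )
    return records


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon/CDS, biotype + species attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            s = gene.span
            fh.write(
                "\t".join(
                    [
                        s.chrom, "baitpond", "gene", str(s.start), str(s.end), ".",
                        s.strand if s.strand != "." else ".", ".",
                        f"ID=gene:{gene.symbol};Name={gene.symbol}",
                    ]
                )
                + "\n"
            )
            for t in gene.transcripts:
                ts = t.span
                attrs = (
                    f"ID=transcript:{t.transcript_id};Parent=gene:{gene.symbol};"
                    f"biotype={t.biotype};species={t.species};principal={int(t.principal)}"
                )
                fh.write(
                    "\t".join(
                        [
                            ts.chrom, "baitpond", "mRNA", str(ts.start), str(ts.end),
                            ".", t.strand if t.strand != "." else ".", ".", attrs,
                        ]
                    )
                    + "\n"
                )
                for j, e in enumerate(t.exons, 1):
                    fh.write(
                        "\t".join(
                            [
                                e.chrom, "baitpond", "exon", str(e.start), str(e.end),
                                ".", t.strand if t.strand != "." else ".", ".",
                                f"ID=exon:{t.transcript_id}.{j};Parent=transcript:{t.transcript_id}",
                            ]
                        )
                        + "\n"
                    )
                if t.cds is not None:
                    for e in t.exons:
                        lo = max(e.start, t.cds.start)
                        hi = min(e.end, t.cds.end)
                        if lo <= hi:
                            fh.write(
                                "\t".join(
                                    [
                                        e.chrom, "baitpond", "CDS", str(lo), str(hi),
                                        ".", t.strand if t.strand != "." else ".", "0",
                                        f"ID=cds:{t.transcript_id};Parent=transcript:{t.transcript_id}",
                                    ]
                                )
                                + "\n"
                            )


def read_gff3(path: str | os.PathLike, default_species: str = "human") -> list[GeneModel]:
    """Read gene models from GFF3 via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        symbol = g.attributes.get("Name", [g.id.split(":")[-1]])[0]
        transcripts = []
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = [
                GenomicInterval(e.seqid, e.start, e.end, e.strand if e.strand in "+-" else ".")
                for e in db.children(t, featuretype="exon", order_by="start")
            ]
            cds_parts = list(db.children(t, featuretype="CDS", order_by="start"))
            cds = None
            if cds_parts:
                cds = GenomicInterval(
                    cds_parts[0].seqid,
                    min(c.start for c in cds_parts),
                    max(c.end for c in cds_parts),
                    cds_parts[0].strand if cds_parts[0].strand in "+-" else ".",
                )
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id.split(":")[-1],
                    gene_symbol=symbol,
                    species=t.attributes.get("species", [default_species])[0],
                    biotype=t.attributes.get("biotype", ["protein_coding"])[0],
                    exons=tuple(exons),
                    cds=cds,
                    principal=t.attributes.get("principal", ["0"])[0] in ("1", "true"),
                )
            )
        genes.append(
            GeneModel(
                symbol=symbol,
                span=GenomicInterval(g.seqid, g.start, g.end, g.strand if g.strand in "+-" else "."),
                transcripts=tuple(transcripts),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    items = seqs.items() if isinstance(seqs, dict) else seqs
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    seqio_write(records, str(path), "fasta")
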