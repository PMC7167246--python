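"""Synthetic pipeline inputs with known ground truth.

The generator emulates every external input the pipeline consumes — GWAS
lead-SNP tables, multi-isoform gene annotation, per-type variation call
sets, local human/ape sequence pairs, and expression matrices — at a
configurable scale, planting hits whose recovery can be checked exactly.

Two presets are provided.  ``small`` (default for tests) builds a few
dozen genes on three chromosomes with planted HIEGs, validation cases and
expression signatures.  ``paper-scale`` reproduces the shape of the
published study inputs: 271 association loci implicating 549 autosomal
bait genes across 22 autosomes, and a variation pond of 1,465 STR
contractions, 4,921 STR expansions, 5,894 deletions, 11,899 insertions,
625 inversions and 218 large HSDs, with 26+74 STR-hit, 144
insertion-carrying, 94 deletion-carrying and 31 inversion-hit bait genes
planted (plus 28 hCONDEL genes and one HSD gene).

Edits are literal plants: no linkage disequilibrium, recombination or
phylogenetic sequence evolution is simulated.  Random streams are
per-component (genome / pond / expression / validation), derived from the
master seed, so regenerating one component does not perturb the others.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import ValidationCase
from .expression import ExpressionMatrix
from .intervals import GenomicInterval
from .records import (
    GeneModel,
    GwasStudy,
    LeadSnp,
    PositionalClass,
    TranscriptModel,
    VariationRecord,
    VariationType,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: The six GWAS the bait-gene stage integrates, with their cohort sizes.
STUDIES = (
    GwasStudy("study1", "general cognitive function meta-analysis", 53949),
    GwasStudy("study2", "cognitive function and educational attainment", 112151),
    GwasStudy("study3", "fluid intelligence meta-analysis", 78308),
    GwasStudy("study4", "cognition meta-analysis, 24 cohorts", 35298),
    GwasStudy("study5", "extremely high intelligence cohort", 1238),
    GwasStudy("study6", "intelligence meta-analysis, 14 cohorts", 269867),
)

NEOCORTEX_REGIONS = ("ACC", "DPFC", "VPFC", "PMC", "V1C")
OTHER_REGIONS = ("HIP", "striatum", "CB")
EXPR_SPECIES = ("human", "chimpanzee", "gorilla", "gibbon")


@dataclass
class ExpressionSpec:
    """Planted structure of the synthetic expression matrices."""

    n_tissues: int = 37
    n_enriched: int = 12          # genes planted with a cortex effect
    enriched_fold: float = 3.0    # multiplicative cortex effect (> 2.057 => ratio > 2)
    species_effect_fold: float = 4.0   # species-specific neocortex signature
    n_signature_genes: int = 3    # genes per species / per non-neocortex tissue
    planted_fold_changes: tuple[float, ...] = (4.8, 0.4)
    noise_sigma: float = 0.0      # gaussian sigma on the log2 scale


@dataclass
class SimulationConfig:
    seed: int = 1
    n_chroms: int = 3
    n_genes: int = 30             # autosomal gene universe
    n_x_genes: int = 2            # X-linked genes fed to (and dropped by) the bait stage
    n_bait: int = 24              # autosomal genes implicated by lead SNPs
    n_loci: int = 10
    n_duplicate_snps: int = 4     # bait genes re-implicated by a second study
    gene_length_range: tuple[int, int] = (2500, 5000)
    isoforms_per_gene_range: tuple[int, int] = (2, 3)
    gene_pitch: int = 25000       # distance between successive gene starts
    pond_counts: dict = field(
        default_factory=lambda: {
            VariationType.STR_CONTRACTION: 4,
            VariationType.STR_EXPANSION: 6,
            VariationType.INSERTION: 10,
            VariationType.DELETION: 8,
            VariationType.HCONDEL: 5,
            VariationType.HSD: 2,
            VariationType.INVERSION: 3,
        }
    )
    planted_prey: dict = field(
        default_factory=lambda: {
            VariationType.STR_CONTRACTION: 1,
            VariationType.STR_EXPANSION: 1,
            VariationType.INSERTION: 2,
            VariationType.DELETION: 1,
            VariationType.HCONDEL: 2,
            VariationType.HSD: 1,
            VariationType.INVERSION: 2,
        }
    )
    #: (bait gene index, variation type, positional class) for exon-level plants
    planted_hieg_spec: list = field(
        default_factory=lambda: [
            (0, VariationType.INSERTION, PositionalClass.CDS_EXON),
            (1, VariationType.INSERTION, PositionalClass.UTR3),
            (2, VariationType.STR_EXPANSION, PositionalClass.NONCODING_EXON),
            (3, VariationType.STR_CONTRACTION, PositionalClass.CDS_EXON),
            (4, VariationType.DELETION, PositionalClass.NONCODING_EXON),
        ]
    )
    plant_exon_gain: bool = True  # one gene with a human-specific gained exon
    false_specific_fraction: float = 0.0  # planted cases whose ape carries the edit
    validation_flank_bp: int = 300
    emit_sequences: bool = True
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def __post_init__(self) -> None:
        for counts in (self.pond_counts, self.planted_prey):
            for v in counts.values():
                if v < 0:
                    raise ValueError("counts must be >= 0")
        if self.expression.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.n_bait > self.n_genes:
            raise ValueError("n_bait cannot exceed n_genes")
        n_planted_genes = sum(self.planted_prey.values()) + len(self.planted_hieg_spec)
        if n_planted_genes + int(self.plant_exon_gain) > self.n_bait:
            raise ValueError("more planted genes than bait genes")
        for vt, n in self.planted_prey.items():
            if self.pond_counts.get(vt, 0) < n:
                raise ValueError(f"pond_counts[{vt}] smaller than planted_prey[{vt}]")


def small_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(seed=seed)


def paper_scale_config(seed: int = 1) -> SimulationConfig:
    """The shape of the published study: 271 loci, 549 bait genes, full pond."""
    return SimulationConfig(
        seed=seed,
        n_chroms=22,
        n_genes=589,              # 549 bait + 40 decoy autosomal genes
        n_x_genes=10,
        n_bait=549,
        n_loci=271,
        n_duplicate_snps=60,
        gene_length_range=(8000, 40000),
        gene_pitch=150000,
        pond_counts={
            VariationType.STR_CONTRACTION: 1465,
            VariationType.STR_EXPANSION: 4921,
            VariationType.DELETION: 5894,
            VariationType.INSERTION: 11899,
            VariationType.INVERSION: 625,
            VariationType.HSD: 218,
            VariationType.HCONDEL: 500,
        },
        planted_prey={
            VariationType.STR_CONTRACTION: 26,
            VariationType.STR_EXPANSION: 74,
            VariationType.INSERTION: 144,
            VariationType.DELETION: 94,
            VariationType.INVERSION: 31,
            VariationType.HSD: 1,
            VariationType.HCONDEL: 28,
        },
        planted_hieg_spec=[],
        plant_exon_gain=False,
        emit_sequences=False,
    )


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """What the pipeline must recover from the generated files."""

    expected_loci: int = 0
    expected_bait_symbols: list = field(default_factory=list)
    expected_prey: list = field(default_factory=list)  # [gene, var_id] pairs
    expected_prey_genes_by_type: dict = field(default_factory=dict)
    expected_hieg: dict = field(default_factory=dict)  # gene -> sorted categories
    expected_enriched: list = field(default_factory=list)
    expected_fold_changes: dict = field(default_factory=dict)
    expected_species_partition: dict = field(default_factory=dict)
    validation_labels: dict = field(default_factory=dict)  # var_id -> bool (truly specific)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Gene construction


@dataclass
class GeneBlueprint:
    """A generated gene plus the windows where variations can be planted."""

    gene: GeneModel
    cds_site: GenomicInterval
    utr5_site: GenomicInterval
    utr3_site: GenomicInterval
    noncoding_site: Optional[GenomicInterval]
    intron_sites: list


def _build_gene(
    symbol: str,
    chrom: str,
    start: int,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    species: str = "human",
) -> GeneBlueprint:
    n_exons = int(rng.integers(4, 8))
    exon_lens = rng.integers(160, 300, size=n_exons)
    target_len = int(rng.integers(*cfg.gene_length_range))
    total_intron = max(target_len - int(exon_lens.sum()), (n_exons - 1) * 350)
    cuts = rng.dirichlet(np.ones(n_exons - 1)) * (total_intron - (n_exons - 1) * 350)
    intron_lens = (cuts + 350).astype(int)
    strand = "+" if rng.random() < 0.5 else "-"
    exons = []
    pos = start
    for i in range(n_exons):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]) - 1, strand))
        pos = exons[-1].end + 1
        if i < n_exons - 1:
            pos += int(intron_lens[i])
    utr5_len = int(rng.integers(80, min(130, exon_lens[0] - 20)))
    utr3_len = int(rng.integers(80, min(130, exon_lens[-1] - 20)))
    cds = GenomicInterval(chrom, exons[0].start + utr5_len, exons[-1].end - utr3_len, strand)
    principal = TranscriptModel(
        transcript_id=f"{symbol}.t1",
        gene_symbol=symbol,
        species=species,
        biotype="protein_coding",
        exons=tuple(exons),
        cds=cds,
        principal=True,
    )
    transcripts = [principal]
    n_isoforms = int(rng.integers(*cfg.isoforms_per_gene_range)) if (
        cfg.isoforms_per_gene_range[0] < cfg.isoforms_per_gene_range[1]
    ) else cfg.isoforms_per_gene_range[0]
    if n_isoforms >= 2 and n_exons >= 5:
        skipped = list(exons[:2]) + list(exons[3:])  # drop the third exon
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{symbol}.t2",
                gene_symbol=symbol,
                species=species,
                biotype="protein_coding",
                exons=tuple(skipped),
                cds=cds,
                principal=False,
            )
        )
    # processed transcript: an extra exon inside the first intron
    intron1 = GenomicInterval(chrom, exons[0].end + 1, exons[1].start - 1, strand)
    noncoding_site = None
    if intron1.length >= 320:
        extra = GenomicInterval(
            chrom, intron1.start + 60, intron1.start + 60 + 139, strand
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{symbol}.t0",
                gene_symbol=symbol,
                species=species,
                biotype="processed_transcript",
                exons=(extra, exons[1]),
                cds=None,
                principal=False,
            )
        )
        noncoding_site = extra
    span = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    gene = GeneModel(symbol=symbol, span=span, transcripts=tuple(transcripts))
    # plant windows
    mid = exons[len(exons) // 2]
    if strand == "+":
        utr5_site = GenomicInterval(chrom, exons[0].start + 5, cds.start - 5, strand)
        utr3_site = GenomicInterval(chrom, cds.end + 5, exons[-1].end - 5, strand)
    else:
        utr3_site = GenomicInterval(chrom, exons[0].start + 5, cds.start - 5, strand)
        utr5_site = GenomicInterval(chrom, cds.end + 5, exons[-1].end - 5, strand)
    # the last intron is free of processed-transcript exons
    last_intron = GenomicInterval(chrom, exons[-2].end + 1, exons[-1].start - 1, strand)
    intron_sites = [
        GenomicInterval(chrom, last_intron.start + 20, last_intron.end - 20, strand)
    ]
    return GeneBlueprint(
        gene=gene,
        cds_site=mid,
        utr5_site=utr5_site,
        utr3_site=utr3_site,
        noncoding_site=noncoding_site,
        intron_sites=intron_sites,
    )


@dataclass
class SyntheticGenome:
    blueprints: list
    chrom_lengths: dict
    sequences: Optional[dict]  # chrom -> str, only when emit_sequences

    @property
    def genes(self) -> list:
        return [bp.gene for bp in self.blueprints]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Generate non-overlapping multi-isoform genes, deterministically per seed."""
    rng = np.random.default_rng([config.seed % (2**31), 1])
    chroms = [str(c + 1) for c in range(config.n_chroms)]
    blueprints: list[GeneBlueprint] = []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    if config.gene_length_range[1] + 10000 > config.gene_pitch:
        raise ValueError("gene_pitch too small for gene_length_range (infeasible packing)")
    idx = 0
    for chrom in chroms:
        for j in range(per_chrom):
            if idx >= config.n_genes:
                break
            start = 50000 + j * config.gene_pitch
            blueprints.append(
                _build_gene(f"G{idx + 1:04d}", chrom, start, rng, config)
            )
            idx += 1
    for k in range(config.n_x_genes):
        start = 50000 + k * config.gene_pitch
        blueprints.append(_build_gene(f"GX{k + 1:02d}", "X", start, rng, config))
    chrom_lengths = {}
    for bp in blueprints:
        c = bp.gene.chrom
        chrom_lengths[c] = max(chrom_lengths.get(c, 0), bp.gene.span.end + 60000)
    sequences = None
    if config.emit_sequences:
        sequences = {c: _random_seq(rng, n) for c, n in sorted(chrom_lengths.items())}
    return SyntheticGenome(
        blueprints=blueprints, chrom_lengths=chrom_lengths, sequences=sequences
    )


# ---------------------------------------------------------------------------
# Pond + GWAS + validation cases


_VAR_SPAN_RANGES = {
    VariationType.STR_CONTRACTION: (20, 60),
    VariationType.STR_EXPANSION: (20, 60),
    VariationType.INSERTION: (55, 90),
}


def _plant_variation(
    vtype: VariationType,
    site: GenomicInterval,
    var_id: str,
    rng: np.random.Generator,
) -> VariationRecord:
    """Place one variation of *vtype* inside (or anchored to) *site*."""
    if vtype in _VAR_SPAN_RANGES:
        lo, hi = _VAR_SPAN_RANGES[vtype]
        span = int(rng.integers(lo, min(hi, max(lo + 1, site.length - 4))))
        start = site.start + max(0, (site.length - span) // 2)
        locus = GenomicInterval(site.chrom, start, start + span - 1)
        return VariationRecord(var_id=var_id, vtype=vtype, locus=locus,
                               length_bp=span, source="synthetic")
    if vtype in (VariationType.DELETION, VariationType.HCONDEL):
        anchor = site.start + site.length // 2
        length = int(rng.integers(100, 3000))
        return VariationRecord(
            var_id=var_id, vtype=vtype,
            locus=GenomicInterval(site.chrom, anchor, anchor),
            length_bp=length, source="synthetic",
        )
    if vtype is VariationType.HSD:
        length = int(rng.integers(5500, 9000))
        locus = GenomicInterval(site.chrom, site.start, site.start + length - 1)
        return VariationRecord(var_id=var_id, vtype=vtype, locus=locus,
                               length_bp=length, source="synthetic")
    raise ValueError(f"cannot plant {vtype}")


@dataclass
class SyntheticInputs:
    """All generated pipeline inputs plus their ground truth."""

    genome: SyntheticGenome
    lead_snps: list
    pond_sources: dict  # VariationType -> [VariationRecord]
    validation_cases: list
    exon_gain_gene: Optional[str]
    ape_transcripts: dict  # species -> [TranscriptModel] for the exon-gain gene
    exon_sequences: dict
    truth: GroundTruth


def _site_for(bp: GeneBlueprint, pclass: PositionalClass) -> GenomicInterval:
    if pclass is PositionalClass.CDS_EXON:
        return bp.cds_site
    if pclass is PositionalClass.UTR5:
        return bp.utr5_site
    if pclass is PositionalClass.UTR3:
        return bp.utr3_site
    if pclass is PositionalClass.NONCODING_EXON:
        if bp.noncoding_site is None:
            raise ValueError(
                f"gene {bp.gene.symbol} has no processed-transcript exon to plant in"
            )
        return bp.noncoding_site
    if pclass is PositionalClass.INTRON:
        return bp.intron_sites[0]
    raise ValueError(f"cannot plant positional class {pclass}")


_CATEGORY_OF_PLANT = {
    VariationType.INSERTION: "indel",
    VariationType.DELETION: "indel",
    VariationType.STR_CONTRACTION: "STR",
    VariationType.STR_EXPANSION: "STR",
    VariationType.HCONDEL: "hCONDEL",
    VariationType.HSD: "HSD",
}


def make_pond_and_gwas(config: SimulationConfig, genome: SyntheticGenome) -> SyntheticInputs:
    """Generate lead SNPs, the per-type pond, validation cases and ground truth."""
    rng = np.random.default_rng([config.seed % (2**31), 2])
    autosomal = [bp for bp in genome.blueprints if bp.gene.chrom != "X"]
    x_linked = [bp for bp in genome.blueprints if bp.gene.chrom == "X"]
    bait_bps = autosomal[: config.n_bait]
    truth = GroundTruth()
    truth.expected_bait_symbols = sorted(bp.gene.symbol for bp in bait_bps)

    # --- lead SNPs: one per bait/X gene, duplicates from a second study
    snp_targets = bait_bps + x_linked
    truth.expected_loci = config.n_loci
    lead_snps: list[LeadSnp] = []
    locus_of = [i % config.n_loci for i in range(len(snp_targets))]
    for i, bp in enumerate(snp_targets):
        g = bp.gene
        pos = g.span.start + int(rng.integers(0, g.span.length))
        study = STUDIES[i % len(STUDIES)].study_id
        lead_snps.append(
            LeadSnp(
                rsid=f"rs{900000 + i}",
                locus=GenomicInterval(g.chrom, pos, pos),
                study_id=study,
                nearest_gene=g.symbol,
                p_value=float(10 ** -rng.uniform(8, 12)),
                locus_id=f"L{locus_of[i] + 1:03d}",
            )
        )
    for j in range(min(config.n_duplicate_snps, len(bait_bps))):
        bp = bait_bps[j]
        g = bp.gene
        pos = g.span.start + int(rng.integers(0, g.span.length))
        other_study = STUDIES[(j + 1) % len(STUDIES)].study_id
        lead_snps.append(
            LeadSnp(
                rsid=f"rs{980000 + j}",
                locus=GenomicInterval(g.chrom, pos, pos),
                study_id=other_study,
                nearest_gene=g.symbol,
                p_value=float(10 ** -rng.uniform(8, 12)),
                locus_id=f"L{locus_of[j] + 1:03d}",
            )
        )

    # --- assign planted genes: HIEG plants first, then per-type prey plants
    pond_sources: dict[VariationType, list[VariationRecord]] = {
        vt: [] for vt in config.pond_counts
    }
    counter = {vt: 0 for vt in VariationType}

    def next_id(vt: VariationType) -> str:
        counter[vt] += 1
        return f"{vt.value}.{counter[vt]:05d}"

    prey_pairs: list[tuple[str, str]] = []
    prey_genes_by_type: dict[str, set] = {vt.value: set() for vt in VariationType}
    hieg_truth: dict[str, set] = {}
    planted_cases: list[tuple[VariationRecord, GeneBlueprint, bool]] = []

    used = set()
    for gene_idx, vtype, pclass in config.planted_hieg_spec:
        bp = bait_bps[gene_idx]
        if bp.gene.symbol in used:
            raise ValueError(f"gene index {gene_idx} planted twice")
        used.add(bp.gene.symbol)
        rec = _plant_variation(vtype, _site_for(bp, pclass), next_id(vtype), rng)
        pond_sources.setdefault(vtype, []).append(rec)
        prey_pairs.append((bp.gene.symbol, rec.var_id))
        prey_genes_by_type[vtype.value].add(bp.gene.symbol)
        hieg_truth.setdefault(bp.gene.symbol, set()).add(_CATEGORY_OF_PLANT[vtype])
        if vtype in (VariationType.INSERTION, VariationType.DELETION,
                     VariationType.HCONDEL):
            planted_cases.append((rec, bp, True))

    free = [bp for bp in bait_bps if bp.gene.symbol not in used]
    exon_gain_gene = None
    ape_transcripts: dict[str, list[TranscriptModel]] = {}
    exon_sequences: dict[tuple, str] = {}
    if config.plant_exon_gain:
        bp = free.pop(0)
        used.add(bp.gene.symbol)
        exon_gain_gene = bp.gene.symbol
        hieg_truth.setdefault(exon_gain_gene, set()).add("exon_gain_loss")

    for vtype in sorted(config.planted_prey, key=lambda v: v.value):
        n = config.planted_prey[vtype]
        for _ in range(n):
            bp = free.pop(0)
            used.add(bp.gene.symbol)
            if vtype is VariationType.INVERSION:
                margin = int(rng.integers(1500, 2500))
                g = bp.gene.span
                locus = GenomicInterval(g.chrom, max(1, g.start - margin), g.end + margin)
                rec = VariationRecord(
                    var_id=next_id(vtype), vtype=vtype, locus=locus,
                    length_bp=locus.length, source="synthetic",
                )
            else:
                rec = _plant_variation(
                    vtype, _site_for(bp, PositionalClass.INTRON), next_id(vtype), rng
                )
            pond_sources.setdefault(vtype, []).append(rec)
            prey_pairs.append((bp.gene.symbol, rec.var_id))
            prey_genes_by_type[vtype.value].add(bp.gene.symbol)
            if vtype in (VariationType.HCONDEL, VariationType.HSD):
                hieg_truth.setdefault(bp.gene.symbol, set()).add(
                    _CATEGORY_OF_PLANT[vtype]
                )

    # --- decoys in intergenic gaps, > 3 kb clear of every gene span
    margin = 3000
    windows_by_chrom: dict[str, list[GenomicInterval]] = {}
    for chrom, length in genome.chrom_lengths.items():
        spans = sorted(
            (bp.gene.span for bp in genome.blueprints if bp.gene.chrom == chrom),
            key=lambda s: s.start,
        )
        windows = []
        cursor = 1
        for s in spans:
            if s.start - margin - 1 >= cursor + 200:
                windows.append(GenomicInterval(chrom, cursor, s.start - margin - 1))
            cursor = s.end + margin + 1
        if length - 1000 >= cursor + 200:
            windows.append(GenomicInterval(chrom, cursor, length - 1000))
        windows_by_chrom[chrom] = windows
    all_windows = [w for ws in windows_by_chrom.values() for w in ws]
    window_weights = np.array([w.length for w in all_windows], dtype=float)
    window_weights /= window_weights.sum()

    def decoy_locus(span_len: int) -> GenomicInterval:
        for _ in range(100):
            w = all_windows[int(rng.choice(len(all_windows), p=window_weights))]
            if w.length >= span_len + 2:
                off = int(rng.integers(0, w.length - span_len))
                return GenomicInterval(w.chrom, w.start + off, w.start + off + span_len - 1)
        raise RuntimeError("no intergenic window large enough for a decoy")

    for vtype, total in config.pond_counts.items():
        n_decoys = total - len(pond_sources.get(vtype, []))
        for _ in range(n_decoys):
            if vtype in (VariationType.DELETION, VariationType.HCONDEL):
                locus = decoy_locus(1)
                length = int(rng.integers(51 if vtype is VariationType.DELETION else 60, 4000))
            elif vtype is VariationType.HSD:
                length = int(rng.integers(5001, 20000))
                locus = decoy_locus(length)
            elif vtype is VariationType.INVERSION:
                length = int(rng.integers(9000, 40000))
                locus = decoy_locus(length)
            elif vtype is VariationType.INSERTION:
                length = int(rng.integers(51, 2000))
                locus = decoy_locus(length)
            else:  # STRs
                length = int(rng.integers(20, 200))
                locus = decoy_locus(length)
            point_typed = vtype in (VariationType.DELETION, VariationType.HCONDEL)
            pond_sources[vtype].append(
                VariationRecord(
                    var_id=next_id(vtype), vtype=vtype, locus=locus,
                    length_bp=length if point_typed else locus.length,
                    source="synthetic",
                )
            )

    # --- exon gain: human variant isoform with an exon absent from ape transcripts
    if exon_gain_gene is not None:
        bp = next(b for b in bait_bps if b.gene.symbol == exon_gain_gene)
        site = bp.intron_sites[0]  # free of processed-transcript exons
        gained = GenomicInterval(site.chrom, site.start, site.start + 59,
                                 bp.gene.span.strand)
        principal = bp.gene.principal_transcript
        variant_exons = tuple(sorted(
            list(principal.exons) + [gained], key=lambda e: e.start
        ))
        variant = TranscriptModel(
            transcript_id=f"{exon_gain_gene}.tv",
            gene_symbol=exon_gain_gene,
            species="human",
            biotype="protein_coding",
            exons=variant_exons,
            cds=principal.cds,
            principal=False,
        )
        new_transcripts = tuple(list(bp.gene.transcripts) + [variant])
        bp.gene = GeneModel(
            symbol=bp.gene.symbol, span=bp.gene.span, transcripts=new_transcripts
        )
        seq_of = {}
        if genome.sequences is not None:
            chrom_seq = genome.sequences[bp.gene.chrom]

            def _seq(iv: GenomicInterval) -> str:
                return chrom_seq[iv.start - 1 : iv.end]

        else:  # sequences not emitted: synthesise per-exon sequences
            local_rng = np.random.default_rng([config.seed % (2**31), 5])

            def _seq(iv: GenomicInterval) -> str:
                key = (iv.start, iv.end)
                if key not in seq_of:
                    seq_of[key] = _random_seq(local_rng, iv.length)
                return seq_of[key]

        processed = next(
            (t for t in bp.gene.transcripts if t.biotype == "processed_transcript"),
            None,
        )
        for sp in ("chimpanzee", "gorilla", "orangutan"):
            ape_ts = [
                TranscriptModel(
                    transcript_id=f"{exon_gain_gene}.{sp[:3]}",
                    gene_symbol=exon_gain_gene,
                    species=sp,
                    biotype="protein_coding",
                    exons=principal.exons,
                    cds=principal.cds,
                    principal=True,
                )
            ]
            if processed is not None:
                # apes share the processed transcript, so only the planted
                # exon is human-specific
                ape_ts.append(
                    TranscriptModel(
                        transcript_id=f"{exon_gain_gene}.{sp[:3]}p",
                        gene_symbol=exon_gain_gene,
                        species=sp,
                        biotype="processed_transcript",
                        exons=processed.exons,
                        cds=None,
                        principal=False,
                    )
                )
            ape_transcripts[sp] = ape_ts
        for t in list(bp.gene.transcripts) + [
            t for ts in ape_transcripts.values() for t in ts
        ]:
            for e in t.exons:
                exon_sequences[(t.transcript_id, e.start, e.end)] = _seq(e)

    # --- validation cases (need sequences)
    cases: list[ValidationCase] = []
    if genome.sequences is not None:
        vrng = np.random.default_rng([config.seed % (2**31), 4])
        n_false = int(round(config.false_specific_fraction * len(planted_cases)))
        flags = [i < n_false for i in range(len(planted_cases))]
        vrng.shuffle(flags)  # type: ignore[arg-type]
        for (rec, bp, _), false_specific in zip(planted_cases, flags):
            case = build_validation_case(
                rec,
                genome.sequences[rec.locus.chrom],
                flank_bp=config.validation_flank_bp,
                rng=vrng,
                false_specific=false_specific,
            )
            cases.append(case)
            truth.validation_labels[rec.var_id] = not false_specific
            if false_specific:
                # a rejected variation drops out of the HIEG set
                sym = bp.gene.symbol
                if sym in hieg_truth:
                    cat = _CATEGORY_OF_PLANT[rec.vtype]
                    hieg_truth[sym].discard(cat)
                    if not hieg_truth[sym]:
                        del hieg_truth[sym]

    truth.expected_prey = [[g, v] for g, v in sorted(prey_pairs)]
    truth.expected_prey_genes_by_type = {
        k: len(v) for k, v in prey_genes_by_type.items() if v
    }
    truth.expected_hieg = {g: sorted(c) for g, c in sorted(hieg_truth.items())}
    return SyntheticInputs(
        genome=genome,
        lead_snps=lead_snps,
        pond_sources=pond_sources,
        validation_cases=cases,
        exon_gain_gene=exon_gain_gene,
        ape_transcripts=ape_transcripts,
        exon_sequences=exon_sequences,
        truth=truth,
    )


def build_validation_case(
    rec: VariationRecord,
    chrom_seq: str,
    flank_bp: int,
    rng: np.random.Generator,
    false_specific: bool = False,
) -> ValidationCase:
    """Construct human/ape local sequences for one insertion- or deletion-type record.

    The ape sequence is the reverse edit of the human one; a
    ``false_specific`` case instead gives the ape the human state, so the
    validator must reject it.
    """
    species = ("chimpanzee", "gorilla", "orangutan")
    if rec.vtype in (VariationType.INSERTION, VariationType.STR_EXPANSION):
        left = chrom_seq[rec.locus.start - 1 - flank_bp : rec.locus.start - 1]
        segment = chrom_seq[rec.locus.start - 1 : rec.locus.end]
        right = chrom_seq[rec.locus.end : rec.locus.end + flank_bp]
        human = left + segment + right
        ape = human if false_specific else left + right
        return ValidationCase(
            var_id=rec.var_id,
            vtype=rec.vtype,
            human_seq=human,
            ape_seqs={sp: ape for sp in species},
            flank_bp=flank_bp,
            insert_offset=len(left),
            insert_length=len(segment),
        )
    if rec.vtype in (VariationType.DELETION, VariationType.HCONDEL,
                     VariationType.STR_CONTRACTION):
        p = rec.locus.start
        left = chrom_seq[max(0, p - 1 - flank_bp) : p - 1]
        right = chrom_seq[p - 1 : p - 1 + flank_bp]
        ancestral = _random_seq(rng, rec.length_bp)
        human = left + right
        ape = (left + right) if false_specific else (left + ancestral + right)
        return ValidationCase(
            var_id=rec.var_id,
            vtype=rec.vtype,
            human_seq=human,
            ape_seqs={sp: ape for sp in species},
            flank_bp=flank_bp,
            ancestral_seq=ancestral,
        )
    raise ValueError(f"no validation case for {rec.vtype}")


def make_validation_panel(
    n_true: int,
    n_false: int,
    seed: int = 1,
    flank_bp: int = 300,
    segment_bp: int = 100,
) -> tuple[list[ValidationCase], dict[str, bool]]:
    """A labelled panel of truly and falsely human-specific insertion cases."""
    rng = np.random.default_rng([seed % (2**31), 7])
    cases, labels = [], {}
    for i in range(n_true + n_false):
        true_specific = i < n_true
        left = _random_seq(rng, flank_bp)
        right = _random_seq(rng, flank_bp)
        segment = _random_seq(rng, segment_bp)
        human = left + segment + right
        ape = left + (segment if not true_specific else "") + right
        var_id = f"panel.{i + 1:04d}"
        cases.append(
            ValidationCase(
                var_id=var_id,
                vtype=VariationType.INSERTION,
                human_seq=human,
                ape_seqs={sp: ape for sp in ("chimpanzee", "gorilla", "orangutan")},
                flank_bp=flank_bp,
                insert_offset=flank_bp,
                insert_length=segment_bp,
            )
        )
        labels[var_id] = true_specific
    return cases, labels


# ---------------------------------------------------------------------------
# Expression


def make_expression(
    config: SimulationConfig, gene_symbols: Sequence[str]
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Generate the human tissue TPM panel and the cross-species brain RPKM panel.

    Lognormal baselines per gene; a multiplicative cortex effect on the
    planted enriched set; species-specific neocortex signatures and shared
    non-neocortex tissue signatures; planted human/non-human fold changes;
    gaussian noise on the log2 scale.  Ground truth carries the enriched
    set, the fold changes, and the species partition of neocortex samples.
    """
    spec = config.expression
    genes = list(gene_symbols)
    rng = np.random.default_rng([config.seed % (2**31), 3])
    truth = GroundTruth()

    # ---- tissue panel (TPM)
    tissues = ["cerebral cortex"] + [f"tissue_{i:02d}" for i in range(1, spec.n_tissues)]
    base = rng.normal(3.0, 1.0, size=len(genes))
    log2 = np.tile(base[:, None], (1, len(tissues)))
    n_enriched = min(spec.n_enriched, len(genes))
    enriched_idx = rng.choice(len(genes), size=n_enriched, replace=False)
    log2[enriched_idx, 0] += np.log2(spec.enriched_fold)
    if spec.noise_sigma > 0:
        log2 = log2 + rng.normal(0.0, spec.noise_sigma, size=log2.shape)
    tpm = pd.DataFrame(2.0 ** log2, index=genes, columns=tissues)
    tpm_samples = pd.DataFrame(
        {
            "tissue": tissues,
            "species": "human",
            "region_class": ["non_brain"] * len(tissues),
        },
        index=pd.Index(tissues, name="sample"),
    )
    tpm_samples.loc["cerebral cortex", "region_class"] = "neocortex"
    tpm_matrix = ExpressionMatrix(values=tpm, samples=tpm_samples, unit="TPM")
    truth.expected_enriched = sorted(genes[i] for i in enriched_idx)

    # ---- cross-species brain panel (RPKM)
    regions = list(NEOCORTEX_REGIONS) + list(OTHER_REGIONS)
    samples = [f"{sp}_{r}" for sp in EXPR_SPECIES for r in regions]
    meta = pd.DataFrame(
        {
            "tissue": [s.split("_", 1)[1] for s in samples],
            "species": [s.split("_", 1)[0] for s in samples],
            "region_class": [
                "neocortex" if s.split("_", 1)[1] in NEOCORTEX_REGIONS else "non_neocortex"
                for s in samples
            ],
        },
        index=pd.Index(samples, name="sample"),
    )
    k = spec.n_signature_genes
    needed = k * (len(EXPR_SPECIES) + len(OTHER_REGIONS)) + len(spec.planted_fold_changes)
    if len(genes) < needed:
        raise ValueError(f"need >= {needed} genes for the planted expression structure")
    order = list(rng.permutation(len(genes)))
    cursor = 0

    def take(n: int) -> list[int]:
        nonlocal cursor
        out = order[cursor : cursor + n]
        cursor += n
        return out

    species_sig = {sp: take(k) for sp in EXPR_SPECIES}
    tissue_sig = {r: take(k) for r in OTHER_REGIONS}
    fc_idx = take(len(spec.planted_fold_changes))

    base2 = rng.normal(3.0, 1.0, size=len(genes))
    log2 = np.tile(base2[:, None], (1, len(samples)))
    effect = np.log2(spec.species_effect_fold)
    for j, s in enumerate(samples):
        sp, region = s.split("_", 1)
        if region in NEOCORTEX_REGIONS:
            for gi in species_sig[sp]:
                log2[gi, j] += effect
            if sp == "human":
                for gi, fc in zip(fc_idx, spec.planted_fold_changes):
                    log2[gi, j] += np.log2(fc)
        else:
            for gi in tissue_sig[region]:
                log2[gi, j] += effect
    if spec.noise_sigma > 0:
        log2 = log2 + rng.normal(0.0, spec.noise_sigma, size=log2.shape)
    rpkm = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    rpkm_matrix = ExpressionMatrix(values=rpkm, samples=meta, unit="RPKM")

    truth.expected_fold_changes = {
        genes[gi]: float(fc) for gi, fc in zip(fc_idx, spec.planted_fold_changes)
    }
    truth.expected_species_partition = {
        sp: sorted(f"{sp}_{r}" for r in NEOCORTEX_REGIONS) for sp in EXPR_SPECIES
    }
    return tpm_matrix, rpkm_matrix, truth


# ---------------------------------------------------------------------------
# File emission


def simulate_to_dir(config: SimulationConfig, outdir: str | os.PathLike) -> GroundTruth:
    """Generate every pipeline input into *outdir* and return the ground truth.

    Files: ``annotation.gff3`` (+ ``ape_<species>.gff3`` and ``exons.fa``
    when an exon gain is planted), ``genome.fa`` (small preset),
    ``lead_snps.tsv``, ``pond_<type>.tsv`` per variation type, ``cases/``
    validation FASTAs, expression TSVs and ``ground_truth.json``.
    """
    from . import io as bpio
    from .alignment import write_case_fasta

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = make_genome(config)
    inputs = make_pond_and_gwas(config, genome)
    bpio.write_gff3(inputs.genome.genes, out / "annotation.gff3")
    if genome.sequences is not None:
        bpio.write_fasta(genome.sequences, out / "genome.fa")
    bpio.write_table(inputs.lead_snps, out / "lead_snps.tsv", schema="lead_snps")
    for vtype, records in sorted(inputs.pond_sources.items(), key=lambda x: x[0].value):
        bpio.write_table(
            sorted(records, key=lambda r: r.var_id),
            out / f"pond_{vtype.value}.tsv",
            schema="pond",
        )
    if inputs.validation_cases:
        cases_dir = out / "cases"
        cases_dir.mkdir(exist_ok=True)
        for case in inputs.validation_cases:
            write_case_fasta(case, cases_dir / f"{case.var_id}.fa")
    if inputs.ape_transcripts:
        for sp, transcripts in inputs.ape_transcripts.items():
            gene = next(
                g for g in inputs.genome.genes if g.symbol == inputs.exon_gain_gene
            )
            ape_gene = GeneModel(
                symbol=gene.symbol, span=gene.span, transcripts=tuple(transcripts)
            )
            bpio.write_gff3([ape_gene], out / f"ape_{sp}.gff3")
        bpio.write_fasta(
            {
                f"{tid}:{start}-{end}": seq
                for (tid, start, end), seq in inputs.exon_sequences.items()
            },
            out / "exons.fa",
        )
    tpm, rpkm, expr_truth = make_expression(
        config, [bp.gene.symbol for bp in genome.blueprints[: config.n_bait]]
    )
    tpm.to_tsv(out / "expression_tpm.tsv", out / "expression_tpm_samples.tsv")
    rpkm.to_tsv(out / "expression_rpkm.tsv", out / "expression_rpkm_samples.tsv")
    truth = inputs.truth
    truth.expected_enriched = expr_truth.expected_enriched
    truth.expected_fold_changes = expr_truth.expected_fold_changes
    truth.expected_species_partition = expr_truth.expected_species_partition
    truth.to_json(out / "ground_truth.json")
    return truth
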