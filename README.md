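# baitpond

Nomination of candidate genes in the evolution of human intelligence by
crossing **intra-species** variation (GWAS loci for intelligence in human
populations) with **inter-species** variation (human-specific structural
variations relative to the great-ape genomes).

The framework is a bait-and-pond screen:

* **bait genes** — genes implicated by intelligence GWAS: lead SNPs from
  several studies carry nearest-gene annotations, which are integrated
  into a non-redundant autosomal gene set with study provenance;
* **variation pond** — the pooled human-specific structural variations:
  STR contractions/expansions, insertions and deletions > 50 bp, hCONDELs
  (sequence lost in the human lineage but conserved in other species),
  human-specific segmental duplications (HSD, > 1 kb at > 90% similarity),
  inversions, and cross-species exon gain/loss events;
* **prey genes** — bait genes physically hit by a pond variation; the
  intersection uses the 1-kb bucket rule (`⌊coordinate/1000⌋` on both gene
  and variation spans), with an exact interval oracle alongside for
  verification;
* **HIEGs** — human intelligence evolution genes: prey genes whose
  variation falls in exonic sequence of any isoform (CDS, UTR, or an exon
  of a non-protein-coding isoform), plus every gene carrying an hCONDEL,
  an HSD, or an exon gain/loss, which admit regardless of position.

Candidate variations are confirmed by Smith–Waterman local alignment of
human flanking sequence against orthologous ape sequence (an inserted
segment must be absent from every ape; a lost ancestral segment must be
present in every ape and absent from human). Candidate expression is
profiled by the cortex-enrichment ratio over a 37-tissue TPM panel
(cortex TPM ÷ mean over all tissues; > 2 is "strongly enriched"), by the
neocortex fold change between human and non-human primates (mean over
human neocortical samples ÷ pooled non-human mean), and by hierarchical
clustering of brain samples under 1 − Pearson distance with average
linkage.

Because the external call sets and expression databases are not shipped,
a first-class synthetic-data generator (`baitpond.simulate`) emulates
every input — annotation, lead-SNP tables, per-type pond files, local
human/ape sequence pairs, and expression matrices — with planted ground
truth at two scales, including a preset with the study's shape (271 loci,
549 bait genes, a 25k-record pond). A transcription of the published
40-gene candidate table ships with the package (`baitpond.load_catalog`).

## Worked example

Run the selection rules over the packaged candidate catalogue:

```python
from baitpond import load_catalog, select_hiegs

cat = load_catalog()
hiegs, counts = select_hiegs(list(cat.calls), list(cat.variations))
print(f"{len(hiegs)} HIEG candidates from {len(cat.variations)} variations "
      f"in {len(cat.gene_spans)} genes")
print({c.value: n for c, n in counts.items()})
```

prints

```
40 HIEG candidates from 47 variations in 40 genes
{'exon_gain_loss': 2, 'hCONDEL': 28, 'HSD': 1, 'indel': 8, 'STR': 4}
```

i.e. 40 non-redundant candidates; two genes carry an exon gain, 28 an
hCONDEL, one an HSD, eight an exon-located insertion/deletion, and four
an exon-located STR. Three genes (AFF3, GNB5, NRXN1) fall in two
categories at once, which is why the per-category gene counts sum to 43.
Each record states why the gene was admitted, e.g.

```
AFF3  ['HSD', 'hCONDEL'] -- HSD (admitted regardless of position); hCONDEL (admitted regardless of position)
ARIH2 ['STR']            -- exon-located insertion (NONCODING_EXON)
```

The whole pipeline can also be driven from the shell on synthetic inputs:

```sh
baitpond --seed 7 run-all --preset small --out demo/
```

which simulates a small study and runs every stage, reporting among other
lines

```
loci: 10  bait genes: 24 (dropped 2 sex-chromosome gene(s))
validated 3/3 case(s)
{"hieg_genes": 9, "category_gene_counts": {"exon_gain_loss": 1, "hCONDEL": 2, "HSD": 1, "indel": 3, "STR": 2}}
```

— the nine recovered HIEGs are exactly the planted ones
(`demo/inputs/ground_truth.json`). Individual stages are available as the
`bait`, `pond`, `overlap`, `validate`, `hieg`, `expression` and
`simulate` subcommands over the TSV/GFF3/FASTA schemas described in the
module docstrings.

## Layout

```
src/baitpond/
  intervals.py   1-based inclusive coordinate primitives
  records.py     domain types (lead SNPs, gene models, variations, ...)
  io.py          TSV schemas, BED conversion, GFF3 (gffutils), FASTA
  bait.py        bait-gene integration and X-chromosome exclusion
  pond.py        variation pond assembly and size filters
  overlap.py     1-kb-bucket intersection + exact interval oracle
  alignment.py   Smith–Waterman confirmation of candidate variations
  hieg.py        positional classification, exon gain/loss, selection
  expression.py  cortex enrichment, fold changes, clustering
  simulate.py    synthetic inputs with planted ground truth
  pipeline.py    in-memory end-to-end driver
  catalog.py     the packaged 40-gene candidate catalogue
  cli.py         the `baitpond` executable
```

See `docs/methods.md` for the modelling choices and their rationale.
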