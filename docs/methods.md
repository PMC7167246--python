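# Methods

## Coordinates and record model

All internal coordinates are 1-based inclusive, the convention of Ensembl
annotation and of the published variation tables this package consumes;
`end − start + 1` is a span's length. BED input (0-based half-open) is
converted on read, so a BED line `chr3 48968204 48968380` becomes the
inclusive span 48968205–48968380 (176 bp). Chromosome labels are
normalised by stripping a `chr` prefix; gene symbols are matched
case-sensitively and exactly.

hCONDELs — and point-anchored deletions generally — are stored as a
single human anchor coordinate plus the length of the ancestral sequence
lost in the human lineage: the human footprint of a clean deletion is a
joint point, while the lost sequence can be kilobases long. Whether the
published anchor marks the 5′ edge or the midpoint of the deletion locus
is not documented; the package treats it as an opaque anchor and never
derives a span from it.

One row of the packaged candidate catalogue is internally inconsistent:
the PCCB exon gain is printed as 136326325–136326385 with length 60,
which is 61 bp inclusive. Printed data are never silently corrected; the
record is stored as printed and flagged via
`Catalog.convention_ambiguous_ids()`. Every other ranged catalogue row
satisfies the inclusive-length identity (e.g. the TRIOBP insertion,
37723443–37724117 = 675 bp).

## Bait genes

Nearest-gene assignments are taken as given from the source GWAS (they
were produced by the original studies' annotation); the package
integrates, it does not re-annotate, and performs no LD clumping or
p-value thresholding. A *locus* is the set of lead SNPs sharing a locus
identifier in the input; a SNP without one is its own locus — the
published integration does not document how overlapping loci from
different studies were merged, so the identifier convention is the
package's stand-in. Integration unions study provenance per gene symbol
and is idempotent. X/Y-linked genes are excluded (several source cohorts
did not impute the X chromosome), with the removed count logged.

## Variation pond

Per-type call sets are pooled with only the size rules the source
definitions impose: insertions/deletions must exceed 50 bp and HSDs 1 kb;
STRs, hCONDELs and inversions enter unfiltered (the published inversion
set spans 9 kb–8.4 Mb). A separate `filter_hsd_large` view applies the
> 5 kb cut used for the large-HSD analysis. An insertion also called as
an STR expansion is stored once, as an insertion with `also_str` set; the
duality is resolved at category-assignment time (STR takes precedence).
Admission is monotone: adding a source never removes admitted records.

## Intersection: the 1-kb bucket rule and its oracle

The operative intersection divides every coordinate by 1000 and calls a
hit when bucket ranges meet on the same chromosome. Read literally this
is an efficiency device, but it changes semantics: a variation up to
999 bp outside a gene span can still share its bucket. Both readings are
preserved — bucket hits carry `within_gene`, the exact-span verdict, and
a brute-force interval oracle (`exact_overlap_oracle`) is provided; exact
hits are provably a subset of bucket hits for any bucket size, with
equality as the bucket shrinks to 1 bp. Full variation spans are
bucketed, not just start coordinates (the alternative would drop hits
from long variations entering a gene from the left). Integer division is
floor on 1-based coordinates.

## Alignment validation

Candidates are confirmed at desk scale by Smith–Waterman local alignment
(biopython's `PairwiseAligner`; match +1, mismatch −2, gap open −5, gap
extend −2 — BLASTn-like scoring). A segment is "found" in a target when
the best local alignment reaches ≥ 90% identity while covering ≥ 80% of
the segment; both thresholds are configurable, and the coverage rule is a
stand-in for an undocumented criterion in the original filter. Identity
thresholds deliberately replace E-values: E-values depend on database
size and are meaningless without a genome-scale database. A variation is
validated only if **every** supplied ape species shows the ancestral
state (inserted segment absent / lost segment present-in-ape and
absent-in-human); species with missing sequence are skipped with a
warning, and an ape sequence shorter than the flank length is an error.
Flanks default to 500 bp per side — long enough to anchor the locus,
short enough that a case aligns in milliseconds. Flank anchoring is not
itself part of the verdict, which keeps the verdict monotone in the
identity threshold for insertion-type cases.

## Gene-structure classification and HIEG selection

Every prey variation is classified against every isoform and the most
consequential class wins: CDS exon > UTR > non-coding-isoform exon >
intron > flank, with UTR side resolved strand-aware.
`nearest_exon_distance` is the smallest gap to any exon of any isoform
(0 = overlapping, 1 = adjacent bases).

"Coding region" is interpreted inclusively — exonic sequence of *any*
isoform, UTRs and processed-transcript exons included — because the
published candidate set itself admits a 3′UTR insertion (GNB5) and
processed-transcript exons (ARIH2, STAB1, TSNARE1). hCONDELs, HSDs and
exon gain/loss events admit their gene regardless of intronic position
(all 28 catalogued hCONDELs are intronic yet admitted, for their lineage
specificity). Categories follow the variation type; an exon-located
insertion flagged `also_str` counts under STR, not indel — the reading
that makes the catalogue's 8 indel + 4 STR gene counts consistent.
Inversions never admit a gene (the category set has no inversion member
and the published set contains none); they are audited separately for
whether any gene span contains an inversion breakpoint. Per-category
gene counts therefore satisfy: sum of counts = unique genes + genes
carrying a second category (43 = 40 + 3 on the catalogue).

Exon gain/loss compares exon sequences across all isoforms intra- and
inter-species with the validator's aligner and thresholds: a human exon
matching no exon of any ape transcript in any supplied species is a
gain; loss is symmetric, making the operation antisymmetric under
swapping the human and ape roles. Principal-isoform flags are taken from
the input annotation.

## Expression profiling

The cortex-enrichment ratio divides cerebral-cortex TPM by the mean over
**all** tissues, cortex included (the published ratio is "relative to the
average in 37 tissues", read literally). Ratios > 1 are enriched, > 2
strongly enriched; both cuts carry a 1e-9 tolerance so that exact-tie
rows (constant genes) are not flagged by float round-off. Strongly
enriched genes are typed into three verbally-described patterns, with
configurable cutoffs chosen here: BROAD (expressed above 1 TPM in ≥ 80%
of tissues), CORTEX_RELATIVE (gene maximum below the median of per-gene
maxima — enriched but at low absolute level), CORTEX_DOMINANT (cortex is
the gene's maximum).

Cross-species neocortex fold change = mean over human neocortical
samples ÷ mean over **pooled** non-human neocortical samples (a single
fold change per gene is reported without per-species detail; per-region
averaging is the exposed alternative). Genes with zero non-human mean
are flagged rather than given a number. Reciprocity holds exactly:
FC(A/B)·FC(B/A) = 1 for positive means.

Clustering uses average linkage on 1 − Pearson correlation distance (the
conventional defaults of the clustering tool the analysis names),
samples sorted by label beforehand so the dendrogram is deterministic
and permutation-invariant up to that tie-break. Zero-variance genes are
dropped with a warning — unless *all* samples are identical, in which
case the matrix is kept and the tree flagged degenerate. The clade
report states, per species, whether its neocortical samples are
monophyletic, and whether cerebellum/striatum/hippocampus group by
tissue across species. Clade purity is the adjusted Rand index between
species labels and a k-species cut of the neocortex-only dendrogram.

## Synthetic data

The generator emulates the pipeline's inputs with literal plants — no
linkage disequilibrium, recombination or phylogenetic sequence evolution
— so passing tests demonstrate that the machinery recovers what was
planted, not that real ape assemblies would yield the published gene
lists. Random streams are per-component (genome, pond/GWAS, expression,
validation), derived from the master seed, so regenerating one component
leaves the others untouched.

Genes are packed non-overlapping at a fixed pitch with multi-isoform
structure: a principal coding isoform (4–7 exons of 160–300 bp, introns
≥ 350 bp, ~100 bp UTRs), optionally an exon-skipping coding isoform, and
a processed transcript contributing an intronic non-coding exon — the
plant site for NONCODING_EXON candidates. Planted variations are placed
so their positional class is guaranteed by construction (and verified in
tests by classifying them); decoys sit ≥ 3 kb from every gene span so
that no decoy can reach a gene even through bucket adjacency. Inversion
plants span their gene entirely with a 1.5–2.5 kb margin, mirroring the
published audit in which no gene sat on an inversion breakpoint.

The `paper-scale` preset fixes the generator at the published input
shape — 271 loci implicating 549 autosomal bait genes (plus X-linked
genes the bait stage must drop and decoy genes no SNP implicates), pond
counts of 1,465/4,921 STR contractions/expansions, 5,894 deletions,
11,899 insertions, 625 inversions and 218 HSDs > 5 kb, and planted
per-type prey gene counts of 26+74 (STR), 144 (insertion), 94
(deletion), 31 (inversion), 28 (hCONDEL) and 1 (HSD). The pond's total
hCONDEL count is not documented; 500 is used. The small preset (3
chromosomes, 30 genes, 24 bait) is the default for tests; it runs end to
end in about a second.

Expression matrices are lognormal: per-gene baselines, a ×3
multiplicative cortex effect on the planted enriched set (ratio
37·f/(36+f) ≈ 2.85 > 2), ×4 species-specific neocortex signatures and
shared non-neocortex tissue signatures (3 genes each in the small
preset), planted human/non-human fold changes (4.8 and 0.4 by default,
the magnitudes the published comparison highlights), and Gaussian noise
on the log2 scale (σ = 0 by default; σ = 0.25 against the ×4 effect is
the signal-to-noise ≥ 4 regime exercised in tests).

## Known limitations

* The genome-scale published results (213 prey genes / 406 variations,
  23 and 12 cortex-enriched genes, the per-gene fold-change lists)
  require the external ape-genome call sets and expression databases and
  are not reproduced; the synthetic presets reproduce the documented
  *input* shape and the planted-recovery properties instead.
* The validator's ≥ 80% coverage rule and the expression pattern cutoffs
  are package choices where the original criteria are undocumented; all
  are configurable.
* Protein-domain analysis and protein multiple alignment are out of
  scope; disease annotations are carried as free text only.
* E-value-based filtering is not implemented (by design, see above), so
  validator verdicts are not numerically comparable to a BLAST run.
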