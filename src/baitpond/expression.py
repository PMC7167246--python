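"""Expression profiling of candidate genes.

Three analyses mirror how HIEG candidates are profiled:

* cortex enrichment over a human multi-tissue TPM panel — each gene's
  cerebral-cortex expression divided by its mean over all tissues
  (cortex included); ratio > 1 is enriched, > 2 strongly enriched;
* cross-species neocortex fold change on an RPKM panel of several brain
  regions in human and non-human primates — mean over human neocortical
  samples divided by the pooled mean over non-human neocortical samples;
* hierarchical clustering of samples (1 - Pearson correlation distance,
  average linkage), with a clade report on whether each species' neocortex
  samples form their own clade while cerebellum/striatum/hippocampus group
  by tissue across species.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

REGION_CLASSES = ("neocortex", "non_neocortex", "non_brain")
UNITS = ("TPM", "RPKM")


@dataclass
class ExpressionMatrix:
    """A gene x sample expression matrix with per-sample metadata.

    ``values``: DataFrame, rows = gene symbols, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``tissue``,
    ``species`` and ``region_class``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("tissue", "species", "region_class"):
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
            if self.samples.loc[list(self.values.columns), col].isna().any():
                raise ValueError(f"sample metadata column {col!r} has missing entries")
        bad = set(self.samples["region_class"]) - set(REGION_CLASSES)
        if bad:
            raise ValueError(f"unknown region_class values: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_where(self, **criteria: str) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        return [s for s in self.values.columns if mask.get(s, False)]

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.rename_axis("gene").to_csv(values_path, sep="\t")
        self.samples.rename_axis("sample").to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, samples_path, unit: str) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, dtype=str)
        return cls(values=values, samples=samples, unit=unit)


class ExpressionPattern(enum.Enum):
    """Verbal expression-pattern types for strongly cortex-enriched genes."""

    CORTEX_DOMINANT = "cortex_dominant"    # high in cortex, low elsewhere
    CORTEX_RELATIVE = "cortex_relative"    # enriched, but low absolute level
    BROAD = "broad"                        # enriched yet expressed in most tissues
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class EnrichmentResult:
    gene_symbol: str
    cortex_value: float
    tissue_mean: float
    ratio: float
    pattern: ExpressionPattern

    #: guards the > 1 and > 2 cuts against float round-off on exact ties
    _TIE_EPS = 1e-9

    @property
    def enriched(self) -> bool:
        return self.ratio > 1.0 + self._TIE_EPS

    @property
    def strongly_enriched(self) -> bool:
        return self.ratio > 2.0 + self._TIE_EPS


def cortex_enrichment(
    expr: ExpressionMatrix,
    cortex_tissue: str = "cerebral cortex",
    expressed_tpm: float = 1.0,
    broad_fraction: float = 0.8,
) -> list[EnrichmentResult]:
    """Score every gene's cortex enrichment over the tissue panel.

    ratio = cortex TPM / mean TPM over *all* tissues (cortex included).
    Results are sorted by ratio, descending.  Pattern typing applies to
    strongly enriched genes (ratio > 2): BROAD when expressed above
    ``expressed_tpm`` in >= ``broad_fraction`` of tissues; CORTEX_RELATIVE
    when the gene's maximum lies below the median of per-gene maxima (low
    absolute level); CORTEX_DOMINANT when cortex is the gene's maximum.
    """
    cortex_samples = expr.samples_where(tissue=cortex_tissue)
    if not cortex_samples:
        raise ValueError(f"no sample with tissue {cortex_tissue!r}")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least two tissues")
    values = expr.values
    cortex = values[cortex_samples].mean(axis=1)
    tissue_mean = values.mean(axis=1)
    median_of_maxima = float(values.max(axis=1).median())
    results = []
    for gene in values.index:
        cv, tm = float(cortex[gene]), float(tissue_mean[gene])
        if tm > 0:
            ratio = cv / tm
        else:
            ratio = 0.0
        if tm <= 0 or ratio <= 2.0 + EnrichmentResult._TIE_EPS:
            pattern = ExpressionPattern.UNDETERMINED
        else:
            row = values.loc[gene]
            if (row > expressed_tpm).mean() >= broad_fraction:
                pattern = ExpressionPattern.BROAD
            elif float(row.max()) < median_of_maxima:
                pattern = ExpressionPattern.CORTEX_RELATIVE
            elif cv >= float(row.max()):
                pattern = ExpressionPattern.CORTEX_DOMINANT
            else:
                pattern = ExpressionPattern.UNDETERMINED
        results.append(
            EnrichmentResult(
                gene_symbol=gene,
                cortex_value=cv,
                tissue_mean=tm,
                ratio=ratio,
                pattern=pattern,
            )
        )
    results.sort(key=lambda r: (-r.ratio, r.gene_symbol))
    return results


def isoform_relative_expression(variant_tpm: float, principal_tpm: float) -> float:
    """Variant-isoform expression as a percentage of the principal isoform."""
    if principal_tpm <= 0:
        raise ValueError("principal isoform TPM must be positive (undefined otherwise)")
    if variant_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    return 100.0 * variant_tpm / principal_tpm


@dataclass(frozen=True)
class FoldChangeResult:
    gene_symbol: str
    fold_change: float
    human_mean: float
    nonhuman_mean: float
    flagged: bool  # zero non-human mean: fold change undefined


def cross_species_neocortex_fc(expr: ExpressionMatrix) -> list[FoldChangeResult]:
    """Per-gene human / non-human neocortex fold change.

    Human neocortical samples are averaged; non-human neocortical samples
    are pooled across species and averaged.  Genes with zero non-human
    mean are flagged (fold change reported as inf/0 by convention).
    """
    human = expr.samples_where(species="human", region_class="neocortex")
    nonhuman = [
        s
        for s in expr.samples_where(region_class="neocortex")
        if expr.samples.loc[s, "species"] != "human"
    ]
    if not human or not nonhuman:
        raise ValueError("need human and non-human neocortex samples")
    hm = expr.values[human].mean(axis=1)
    nm = expr.values[nonhuman].mean(axis=1)
    out = []
    for gene in expr.values.index:
        h, n = float(hm[gene]), float(nm[gene])
        if n == 0:
            fc = float("inf") if h > 0 else 0.0
            flagged = True
        else:
            fc, flagged = h / n, False
        out.append(
            FoldChangeResult(
                gene_symbol=gene, fold_change=fc, human_mean=h,
                nonhuman_mean=n, flagged=flagged,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hierarchical clustering


@dataclass
class ClusterResult:
    """Dendrogram over samples plus a clade report.

    ``species_neocortex_monophyly``: per species, whether its neocortex
    samples form a clade; ``tissue_grouping``: for each non-neocortex brain
    tissue, whether its samples group together across species.
    """

    linkage: np.ndarray
    sample_order: list[str]
    species_neocortex_monophyly: dict[str, bool] = field(default_factory=dict)
    tissue_grouping: dict[str, bool] = field(default_factory=dict)
    dropped_genes: list[str] = field(default_factory=list)
    degenerate: bool = False


def _leaf_sets(linkage: np.ndarray, n: int) -> list[frozenset[int]]:
    sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(linkage):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + i] = merged
        out.append(merged)
    return out


def _is_clade(target: frozenset[int], clades: list[frozenset[int]]) -> bool:
    if len(target) <= 1:
        return True
    return target in clades


def cluster_samples(
    expr: ExpressionMatrix,
    nonneocortex_tissues: Sequence[str] = ("CB", "striatum", "HIP"),
) -> ClusterResult:
    """Average-linkage clustering of samples under 1 - Pearson distance.

    Samples are ordered by label before clustering so the dendrogram is
    deterministic and permutation-invariant up to that tie-break.
    Zero-variance genes are dropped with a warning; fewer than two genes
    left, or fewer than three samples, is an error.  An all-identical
    matrix yields a deterministic tree flagged degenerate.
    """
    sample_labels = sorted(expr.values.columns)
    if len(sample_labels) < 3:
        raise ValueError("need at least 3 samples to cluster")
    mat = expr.values[sample_labels]
    variances = mat.var(axis=1)
    dropped = [g for g in mat.index if variances[g] == 0]
    if len(dropped) == mat.shape[0]:
        # all samples identical: keep the matrix, the tree is degenerate
        dropped = []
    elif dropped:
        logger.warning("dropping %d zero-variance gene(s) before clustering", len(dropped))
        mat = mat.drop(index=dropped)
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 genes left after the variance filter")
    # observations = samples, features = genes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        dist = pdist(mat.to_numpy().T, metric="correlation")
    dist = np.nan_to_num(dist, nan=0.0)
    degenerate = bool(np.allclose(dist, 0.0))
    linkage = hierarchy.linkage(dist, method="average")
    clades = _leaf_sets(linkage, len(sample_labels))
    index_of = {s: i for i, s in enumerate(sample_labels)}
    meta = expr.samples
    monophyly: dict[str, bool] = {}
    for species in sorted(set(meta.loc[sample_labels, "species"])):
        neo = [
            s
            for s in sample_labels
            if meta.loc[s, "species"] == species
            and meta.loc[s, "region_class"] == "neocortex"
        ]
        if neo:
            monophyly[species] = _is_clade(
                frozenset(index_of[s] for s in neo), clades
            )
    tissue_grouping: dict[str, bool] = {}
    for tissue in nonneocortex_tissues:
        members = [s for s in sample_labels if meta.loc[s, "tissue"] == tissue]
        if members:
            tissue_grouping[tissue] = _is_clade(
                frozenset(index_of[s] for s in members), clades
            )
    return ClusterResult(
        linkage=linkage,
        sample_order=sample_labels,
        species_neocortex_monophyly=monophyly,
        tissue_grouping=tissue_grouping,
        dropped_genes=dropped,
        degenerate=degenerate,
    )


def neocortex_clade_purity(expr: ExpressionMatrix, n_species: Optional[int] = None) -> float:
    """Adjusted Rand index between species labels and cluster labels of
    the neocortex samples, clustered on their own at k = number of species."""
    from sklearn.metrics import adjusted_rand_score

    neo = sorted(expr.samples_where(region_class="neocortex"))
    species = [expr.samples.loc[s, "species"] for s in neo]
    k = n_species or len(set(species))
    mat = expr.values[neo]
    mat = mat[mat.var(axis=1) > 0]
    dist = pdist(mat.to_numpy().T, metric="correlation")
    linkage = hierarchy.linkage(np.nan_to_num(dist, nan=0.0), method="average")
    labels = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return float(adjusted_rand_score(species, labels))


def plot_expression_heatmap(expr: ExpressionMatrix, path, log_scale: bool = True) -> None:
    """Save a clustered gene x sample heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    result = cluster_samples(expr)
    order = hierarchy.leaves_list(result.linkage)
    samples = [result.sample_order[i] for i in order]
    mat = expr.values[samples].to_numpy(dtype=float)
    if log_scale:
        mat = np.log2(mat + 1.0)
    fig, ax = plt.subplots(
        figsize=(max(6, 0.3 * len(samples)), max(4, 0.2 * mat.shape[0]))
    )
    im = ax.imshow(mat, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(samples)), samples, rotation=90, fontsize=6)
    ax.set_yticks(range(mat.shape[0]), expr.values.index, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"log2({expr.unit}+1)" if log_scale else expr.unit)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
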