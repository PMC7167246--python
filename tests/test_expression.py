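"""Cortex enrichment, cross-species fold changes, and sample clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from baitpond.expression import (
    ExpressionMatrix,
    cluster_samples,
    cortex_enrichment,
    cross_species_neocortex_fc,
    isoform_relative_expression,
    neocortex_clade_purity,
)


def _tissue_matrix(values: dict, tissues=None):
    tissues = tissues or ["cerebral cortex"] + [f"tissue_{i:02d}" for i in range(1, 37)]
    df = pd.DataFrame(values, index=tissues).T
    meta = pd.DataFrame(
        {"tissue": tissues, "species": "human", "region_class": "non_brain"},
        index=pd.Index(tissues, name="sample"),
    )
    meta.loc["cerebral cortex", "region_class"] = "neocortex"
    return ExpressionMatrix(values=df, samples=meta, unit="TPM")


class TestCortexEnrichment:
    def test_forced_arithmetic(self):
        # cortex 10, 36 other tissues at mean-preserving values
        row = [10.0] + [4.0 - 6.0 / 36] * 36  # overall mean = 4
        expr = _tissue_matrix({"G1": row})
        (r,) = cortex_enrichment(expr)
        assert r.ratio == pytest.approx(2.5)
        assert r.strongly_enriched

    def test_uniform_gene_ratio_one(self):
        expr = _tissue_matrix({"G1": [7.5] * 37})
        (r,) = cortex_enrichment(expr)
        assert r.ratio == pytest.approx(1.0)
        assert not r.enriched

    def test_planted_twofold_set_flagged_exactly(self, small_sim):
        from baitpond.simulate import make_expression

        cfg, genome, inputs = small_sim
        tpm, _, truth = make_expression(cfg, inputs.truth.expected_bait_symbols)
        results = cortex_enrichment(tpm)
        strong = sorted(r.gene_symbol for r in results if r.strongly_enriched)
        assert strong == truth.expected_enriched
        assert len(strong) == cfg.expression.n_enriched

    def test_sorted_by_ratio_descending(self, small_sim):
        from baitpond.simulate import make_expression

        cfg, _, inputs = small_sim
        tpm, _, _ = make_expression(cfg, inputs.truth.expected_bait_symbols)
        ratios = [r.ratio for r in cortex_enrichment(tpm)]
        assert ratios == sorted(ratios, reverse=True)

    @given(scale=st.floats(0.01, 1000.0))
    def test_ratio_invariant_under_row_scaling(self, scale):
        row = [10.0, 2.0, 4.0, 8.0, 1.0]
        tissues = ["cerebral cortex", "a", "b", "c", "d"]
        base = _tissue_matrix({"G1": row}, tissues)
        scaled = _tissue_matrix({"G1": [v * scale for v in row]}, tissues)
        r0 = cortex_enrichment(base)[0].ratio
        r1 = cortex_enrichment(scaled)[0].ratio
        assert r1 == pytest.approx(r0, rel=1e-9)

    def test_missing_cortex_sample_is_error(self):
        expr = _tissue_matrix({"G1": [1.0] * 5}, ["a", "b", "c", "d", "e"])
        with pytest.raises(ValueError, match="cerebral cortex"):
            cortex_enrichment(expr)


class TestIsoformRelativeExpression:
    def test_forced_arithmetic(self):
        assert isoform_relative_expression(2.1, 10.0) == pytest.approx(21.0)
        assert isoform_relative_expression(0.0, 10.0) == 0.0

    def test_zero_principal_flagged(self):
        with pytest.raises(ValueError):
            isoform_relative_expression(1.0, 0.0)

    def test_lognormal_noise_recovers_planted_ratio(self):
        # planted 0.21 variant/principal ratio, sigma 0.05, 10 sample pairs
        rng = np.random.default_rng(17)
        principal = 10.0 * np.exp(rng.normal(0, 0.05, size=10))
        variant = 0.21 * 10.0 * np.exp(rng.normal(0, 0.05, size=10))
        estimates = [
            isoform_relative_expression(v, p) for v, p in zip(variant, principal)
        ]
        assert abs(float(np.mean(estimates)) - 21.0) <= 3.0


def _brain_matrix(values: pd.DataFrame):
    meta = pd.DataFrame(
        {
            "tissue": [s.split("_", 1)[1] for s in values.columns],
            "species": [s.split("_", 1)[0] for s in values.columns],
            "region_class": [
                "neocortex" if s.split("_", 1)[1] in
                ("ACC", "DPFC", "VPFC", "PMC", "V1C") else "non_neocortex"
                for s in values.columns
            ],
        },
        index=pd.Index(values.columns, name="sample"),
    )
    return ExpressionMatrix(values=values, samples=meta, unit="RPKM")


class TestFoldChange:
    def _expr(self, human, nonhuman):
        cols = [f"{sp}_{r}" for sp in ("human", "chimpanzee") for r in ("ACC", "V1C")]
        vals = pd.DataFrame(
            [[human, human, nonhuman, nonhuman]], index=["G1"], columns=cols
        )
        return _brain_matrix(vals)

    def test_forced_values(self):
        (r,) = cross_species_neocortex_fc(self._expr(2.0, 4.0))
        assert r.fold_change == pytest.approx(0.5)
        (r,) = cross_species_neocortex_fc(self._expr(3.0, 3.0))
        assert r.fold_change == pytest.approx(1.0)

    def test_planted_fold_changes_recovered_exactly(self, small_sim):
        from baitpond.simulate import make_expression

        cfg, _, inputs = small_sim
        _, rpkm, truth = make_expression(cfg, inputs.truth.expected_bait_symbols)
        fcs = {r.gene_symbol: r.fold_change for r in cross_species_neocortex_fc(rpkm)}
        for gene, fc in truth.expected_fold_changes.items():
            assert fcs[gene] == pytest.approx(fc, rel=1e-9)

    def test_zero_nonhuman_mean_flagged(self):
        (r,) = cross_species_neocortex_fc(self._expr(2.0, 0.0))
        assert r.flagged

    def test_reciprocity(self, small_sim):
        # FC(A/B) x FC(B/A) = 1 for genes with positive means
        from baitpond.simulate import make_expression

        cfg, _, inputs = small_sim
        _, rpkm, _ = make_expression(cfg, inputs.truth.expected_bait_symbols)
        forward = cross_species_neocortex_fc(rpkm)
        swapped_meta = rpkm.samples.copy()
        is_h = swapped_meta["species"] == "human"
        swapped_meta.loc[is_h, "species"] = "nonhuman_pool"
        swapped_meta.loc[~is_h, "species"] = "human"
        swapped = ExpressionMatrix(values=rpkm.values, samples=swapped_meta, unit="RPKM")
        backward = {r.gene_symbol: r for r in cross_species_neocortex_fc(swapped)}
        for r in forward:
            if not r.flagged and r.human_mean > 0:
                assert r.fold_change * backward[r.gene_symbol].fold_change == pytest.approx(
                    1.0, abs=1e-9
                )


class TestClustering:
    def test_planted_species_signatures_give_pure_clades(self, small_sim):
        from baitpond.simulate import make_expression

        cfg, _, inputs = small_sim
        _, rpkm, truth = make_expression(cfg, inputs.truth.expected_bait_symbols)
        result = cluster_samples(rpkm)
        assert all(result.species_neocortex_monophyly.values())
        assert all(result.tissue_grouping.values())
        assert set(result.species_neocortex_monophyly) == set(
            truth.expected_species_partition
        )

    def test_duplicated_sample_merges_first(self):
        rng = np.random.default_rng(0)
        cols = ["human_ACC", "human_HIP", "chimpanzee_ACC", "chimpanzee_HIP"]
        vals = pd.DataFrame(rng.lognormal(1, 1, size=(6, 4)), columns=cols,
                            index=[f"G{i}" for i in range(6)])
        vals["chimpanzee_HIP"] = vals["chimpanzee_ACC"]  # duplicate
        result = cluster_samples(_brain_matrix(vals))
        a = result.sample_order.index("chimpanzee_ACC")
        b = result.sample_order.index("chimpanzee_HIP")
        first = result.linkage[0]
        assert {int(first[0]), int(first[1])} == {a, b}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_samples_degenerate_but_deterministic(self):
        cols = ["human_ACC", "human_HIP", "chimpanzee_ACC"]
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0], [5.0, 5.0, 5.0], [2.0, 2.0, 2.0]],
            columns=cols, index=["G1", "G2", "G3"],
        )
        r1 = cluster_samples(_brain_matrix(vals))
        r2 = cluster_samples(_brain_matrix(vals))
        assert r1.degenerate
        assert np.array_equal(r1.linkage, r2.linkage)

    def test_zero_variance_genes_dropped_and_too_few_is_error(self):
        cols = ["human_ACC", "human_HIP", "chimpanzee_ACC"]
        vals = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
            columns=cols, index=["Gflat", "G2", "G3"],
        )
        result = cluster_samples(_brain_matrix(vals))
        assert result.dropped_genes == ["Gflat"]
        one_left = vals.iloc[[0, 1]]  # one flat gene, one informative gene
        with pytest.raises(ValueError, match="fewer than 2 genes"):
            cluster_samples(_brain_matrix(one_left))

    def test_permutation_invariance_up_to_tie_break(self, small_sim):
        from baitpond.simulate import make_expression

        cfg, _, inputs = small_sim
        _, rpkm, _ = make_expression(cfg, inputs.truth.expected_bait_symbols)
        shuffled = ExpressionMatrix(
            values=rpkm.values[list(reversed(rpkm.values.columns))],
            samples=rpkm.samples,
            unit="RPKM",
        )
        r1, r2 = cluster_samples(rpkm), cluster_samples(shuffled)
        assert r1.sample_order == r2.sample_order
        assert np.allclose(r1.linkage, r2.linkage)

    def test_purity_one_at_high_snr_in_19_of_20_seeds(self):
        # species effect 4x baseline, sigma 0.25 => log2 SNR 8
        from baitpond.simulate import make_expression, small_config

        ok = 0
        for seed in range(20):
            cfg = small_config(seed)
            cfg.expression.noise_sigma = 0.25
            genes = [f"G{i:04d}" for i in range(1, cfg.n_bait + 1)]
            _, rpkm, _ = make_expression(cfg, genes)
            if neocortex_clade_purity(rpkm) == 1.0:
                ok += 1
        assert ok >= 19
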