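import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnfc import (ExpressionMatrix, builtin_minimal_panel, compute_cnfc,
                  cpm_normalize, log_transform, map_panel,
                  median_module_expression, panel_agreement, score_modules,
                  stage_fold_change, zscore_genes)
from cnfc.registry import GeneModule, ModulePanel
from cnfc.scoring import ModuleScoreTable


def _zmatrix(rows, genes, samples, meta=None):
    return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=samples),
                            "zscore", meta=meta if meta is not None else pd.DataFrame())


def _score_table(E, T, I, P=None):
    data = {"excitability": E, "trophic_metabolic": T, "injury_inflammation": I}
    role_of = {k: k for k in data}
    if P is not None:
        data["plasticity"] = P
        role_of["plasticity"] = "plasticity"
    return ModuleScoreTable(
        scores=pd.DataFrame(data, index=[f"s{i}" for i in range(len(E))]),
        role_of=role_of)


class TestZscoreGenes:
    def _mat(self, row, scale="log_intensity"):
        return ExpressionMatrix(
            pd.DataFrame([row], index=["g"], columns=[f"s{i}" for i in range(len(row))]),
            scale)

    def test_unit_spaced_triple(self):
        out = zscore_genes(self._mat([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.values.to_numpy()[0], [-1, 0, 1])
        assert out.scale == "zscore"

    def test_zero_variance_becomes_zero(self):
        out = zscore_genes(self._mat([5.0, 5.0, 5.0]))
        np.testing.assert_array_equal(out.values.to_numpy()[0], [0, 0, 0])

    def test_sample_sd_denominator(self):
        out = zscore_genes(self._mat([2.0, 4.0, 6.0, 8.0]))
        np.testing.assert_allclose(
            out.values.to_numpy()[0], [-1.1619, -0.3873, 0.3873, 1.1619], atol=1e-4)

    def test_group_by_standardizes_within_strata(self):
        values = pd.DataFrame([[1.0, 3.0, 10.0, 30.0]], index=["g"],
                              columns=["a1", "a2", "b1", "b2"])
        meta = pd.DataFrame({"segment": ["A", "A", "B", "B"]}, index=values.columns)
        out = zscore_genes(ExpressionMatrix(values, "log_intensity", meta),
                           group_by="segment")
        block = out.values.to_numpy()[0]
        np.testing.assert_allclose(block[:2].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(block[2:].mean(), 0, atol=1e-12)

    def test_singleton_group_errors(self):
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"],
                              columns=["a1", "a2", "b1"])
        meta = pd.DataFrame({"segment": ["A", "A", "B"]}, index=values.columns)
        with pytest.raises(ValueError, match="single sample"):
            zscore_genes(ExpressionMatrix(values, "log_intensity", meta),
                         group_by="segment")


class TestScoreModules:
    def test_mean_of_mapped_z(self):
        z = _zmatrix([[1.0], [-1.0], [2.0], [0.0]], ["g1", "g2", "g3", "g4"], ["s"])
        panel = ModulePanel([GeneModule("m", ["g1", "g2"]),
                             GeneModule("m2", ["g3", "g4", "gX"])])
        table = score_modules(z, map_panel(panel, z, min_mapped=2))
        assert table.scores.loc["s", "m"] == 0.0
        assert table.scores.loc["s", "m2"] == 1.0  # gX unmapped, excluded

    def test_under_min_mapped_is_missing(self):
        z = _zmatrix([[1.0]], ["g1"], ["s"])
        panel = ModulePanel([GeneModule("m", ["g1", "gX", "gY"])])
        table = score_modules(z, map_panel(panel, z, min_mapped=3))
        assert np.isnan(table.scores.loc["s", "m"])


class TestComputeCnfc:
    def test_composite_arithmetic(self):
        t = compute_cnfc(_score_table([1.2, 0.0], [0.3, 0.0], [0.5, 0.0]))
        np.testing.assert_allclose(t.cnfc.to_numpy(), [1.0, 0.0], atol=1e-12)

    def test_custom_weights(self):
        t = compute_cnfc(_score_table([1.2], [0.3], [0.5]),
                         weights={"excitability": 2})
        assert t.cnfc.iloc[0] == pytest.approx(2.2)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_cnfc(_score_table([1.0], [0.0], [0.0]),
                         weights={"injury_inflammation": -1})

    def test_plasticity_never_enters(self):
        base = compute_cnfc(_score_table([1.0], [1.0], [1.0], P=[0.0]))
        shifted = compute_cnfc(_score_table([1.0], [1.0], [1.0], P=[99.0]))
        assert base.cnfc.iloc[0] == shifted.cnfc.iloc[0]

    def test_injury_strictly_decreases_excitability_increases(self):
        base = compute_cnfc(_score_table([1.0], [1.0], [1.0])).cnfc.iloc[0]
        more_injury = compute_cnfc(_score_table([1.0], [1.0], [1.5])).cnfc.iloc[0]
        more_excit = compute_cnfc(_score_table([1.5], [1.0], [1.0])).cnfc.iloc[0]
        assert more_injury < base < more_excit

    def test_missing_module_propagates_to_nan(self):
        t = compute_cnfc(_score_table([1.0], [np.nan], [0.0]))
        assert np.isnan(t.cnfc.iloc[0])


class TestAffineAndPermutationInvariance:
    @given(c=st.floats(0.1, 50), b=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_gene_affine_invariance(self, c, b):
        """Scaling/shifting any gene row before z-scoring leaves scores unchanged."""
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(0, 1, (6, 8)),
                              index=[f"g{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(8)])
        panel = ModulePanel([GeneModule("excitability", ["g0", "g1"], "excitability"),
                             GeneModule("trophic_metabolic", ["g2", "g3"], "trophic_metabolic"),
                             GeneModule("injury_inflammation", ["g4", "g5"], "injury_inflammation")])
        m1 = ExpressionMatrix(values, "log_intensity")
        mod = values.copy()
        mod.loc["g0"] = c * mod.loc["g0"] + b
        m2 = ExpressionMatrix(mod, "log_intensity")
        t1 = compute_cnfc(score_modules(zscore_genes(m1), map_panel(panel, m1, min_mapped=2)))
        t2 = compute_cnfc(score_modules(zscore_genes(m2), map_panel(panel, m2, min_mapped=2)))
        np.testing.assert_allclose(t1.cnfc.to_numpy(), t2.cnfc.to_numpy(), atol=1e-9)

    def test_gene_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(6)
        values = pd.DataFrame(rng.normal(0, 1, (6, 8)),
                              index=[f"g{i}" for i in range(6)],
                              columns=[f"s{i}" for i in range(8)])
        panel = ModulePanel([GeneModule("excitability", ["g0", "g1"], "excitability"),
                             GeneModule("trophic_metabolic", ["g2", "g3"], "trophic_metabolic"),
                             GeneModule("injury_inflammation", ["g4", "g5"], "injury_inflammation")])
        perm = values.iloc[::-1, ::-1]
        m1, m2 = ExpressionMatrix(values, "log_intensity"), ExpressionMatrix(perm, "log_intensity")
        t1 = compute_cnfc(score_modules(zscore_genes(m1), map_panel(panel, m1, min_mapped=2)))
        t2 = compute_cnfc(score_modules(zscore_genes(m2), map_panel(panel, m2, min_mapped=2)))
        np.testing.assert_allclose(t1.cnfc.sort_index().to_numpy(),
                                   t2.cnfc.sort_index().to_numpy(), atol=1e-12)


class TestMedianModuleExpression:
    def test_median_and_single_gene(self):
        values = pd.DataFrame({"s": [1.0, 2.0, 9.0, 7.0]},
                              index=["g1", "g2", "g3", "g4"])
        m = ExpressionMatrix(values, "log2cpm")
        panel = ModulePanel([GeneModule("m", ["g1", "g2", "g3"]),
                             GeneModule("single", ["g4"])])
        med = median_module_expression(m, map_panel(panel, m, min_mapped=1))
        assert med.loc["s", "m"] == 2.0
        assert med.loc["s", "single"] == 7.0


class TestPanelAgreement:
    def test_identical_and_negated(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert panel_agreement(s, s)[0] == pytest.approx(1.0)
        assert panel_agreement(s, -s)[0] == pytest.approx(-1.0)

    def test_pearson_value(self):
        full = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        minimal = pd.Series([1.0, 2.0, 4.0], index=list("abc"))
        r, n = panel_agreement(full, minimal)
        assert r == pytest.approx(0.9820, abs=1e-4)
        assert n == 3

    def test_constant_vector_is_missing(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        const = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        assert np.isnan(panel_agreement(s, const)[0])


class TestStageFoldChange:
    def _dev_matrix(self):
        values = pd.DataFrame(
            {"E16_r1": [64010.0, 46.0, 4184.0], "P7_r1": [13857.0, 111.0, 1406.0]},
            index=["Cfl1", "Cdk5", "Mcl1"])
        meta = pd.DataFrame({"stage": ["E16", "P7"], "fraction": ["EGFP+", "EGFP+"]},
                            index=values.columns)
        return ExpressionMatrix(values, "cpm", meta)

    def test_ratio_and_presentation_rounding(self):
        fc = stage_fold_change(self._dev_matrix(), "E16", "P7",
                               group="EGFP+", group_key="fraction")
        assert fc.loc["Cfl1", "ratio_2dp"] == 0.22
        assert fc.loc["Cdk5", "ratio_2dp"] == 2.41
        assert fc.loc["Cfl1", "ratio"] == pytest.approx(13857 / 64010)

    def test_replicates_averaged_before_ratio(self):
        values = pd.DataFrame(
            {"a1": [10.0], "a2": [30.0], "b1": [40.0]}, index=["g"])
        meta = pd.DataFrame({"stage": ["A", "A", "B"]}, index=values.columns)
        fc = stage_fold_change(ExpressionMatrix(values, "cpm", meta), "A", "B")
        assert fc.loc["g", "ratio"] == pytest.approx(2.0)  # 40 / mean(10,30)

    def test_zero_baseline_flagged_undefined(self):
        values = pd.DataFrame({"a": [0.0], "b": [5.0]}, index=["g"])
        meta = pd.DataFrame({"stage": ["A", "B"]}, index=values.columns)
        fc = stage_fold_change(ExpressionMatrix(values, "cpm", meta), "A", "B")
        assert np.isnan(fc.loc["g", "ratio"])
        assert bool(fc.loc["g", "undefined"])


def test_mean_vs_median_cnfc_trajectories_agree(dev_dataset):
    """Swapping the across-gene aggregator (mean vs median of log2(CPM+1))
    leaves the composite trajectory essentially unchanged."""
    m, meta, truth, panel = dev_dataset
    logm = log_transform(cpm_normalize(m))
    mapped = map_panel(panel, logm)
    med = median_module_expression(logm, mapped)
    mean = pd.DataFrame(
        {mod.name: logm.values.loc[mod.genes].mean(axis=0) for mod in mapped})
    med_c = (med["excitability"] + med["trophic_metabolic"]
             - med["injury_inflammation"])
    mean_c = (mean["excitability"] + mean["trophic_metabolic"]
              - mean["injury_inflammation"])
    r = np.corrcoef(med_c, mean_c)[0, 1]
    assert r > 0.9
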