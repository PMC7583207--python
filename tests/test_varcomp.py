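"""Variance-components kernel, variant fits, AIC comparison, share curves."""

import math

import numpy as np
import pandas as pd
import pytest

from famclock.data import FamilyDataset
from famclock.likelihood import FitResult
from famclock.simulate import (
    DEFAULT_AE_PARAMS,
    DEFAULT_CE_PARAMS,
    generate_cohort,
    lifespan_pairs_cohort,
)
from famclock.varcomp import (
    Variant,
    VarianceModelSpec,
    compare_variants,
    cov_pair,
    fit_variance_model,
    variance_proportion_curves,
)

CE_VALUES = {"betaC_MZ": 1.41, "betaC_PO": 1.0 / 2.03, "lamC": 0.03, "nuC": 0.005}


class TestCovKernel:
    def test_zero_time_no_constant_term_gives_zero(self):
        v = cov_pair(0.0, 18.0, 1.0, Variant.COHAB_CE, CE_VALUES, group="MZ")
        assert v == pytest.approx(0.0)

    def test_ae_is_constant_in_age(self):
        vals = {"sigmaA2": 0.52}
        covs = [cov_pair(t, 18.0, 1.0, Variant.AE, vals, group="MZ") for t in (0, 18, 80)]
        assert covs == pytest.approx([0.52, 0.52, 0.52])

    def test_ce_mz_value_at_18(self):
        # 1.41 * (1 - exp(-0.54)) evaluated independently = 0.58832 (5 d.p.)
        v = cov_pair(18.0, 18.0, 1.0, Variant.COHAB_CE, CE_VALUES, group="MZ")
        assert v == pytest.approx(0.58832, abs=5e-6)

    def test_mz_dz_ratio_constant_while_cohabiting(self):
        for t in (3.0, 9.0, 15.0):
            mz = cov_pair(t, 18.0, 1.0, Variant.COHAB_CE, CE_VALUES, group="MZ")
            dz = cov_pair(t, 18.0, 0.5, Variant.COHAB_CE, CE_VALUES, group="DZSIB")
            assert mz / dz == pytest.approx(1.41, abs=1e-12)

    @pytest.mark.parametrize("variant,vals", [
        (Variant.AE, {"sigmaA2": 0.4}),
        (Variant.COHAB_AE, {"lamA": 0.04, "nuA": 0.01}),
        (Variant.COHAB_ACE, {"lamA": 0.04, "nuA": 0.01, "lamC": 0.03, "nuC": 0.005}),
        (Variant.COHAB_CE, CE_VALUES),
        (Variant.COHAB_CE_PLUS_A, {"sigmaA2": 0.13, **CE_VALUES}),
    ])
    def test_continuous_at_t0_for_every_variant(self, variant, vals):
        for group, k2 in (("MZ", 1.0), ("DZSIB", 0.5), ("PO", 0.5)):
            lo = cov_pair(18.0 - 1e-11, 18.0, k2, variant, vals, group)
            hi = cov_pair(18.0 + 1e-11, 18.0, k2, variant, vals, group)
            assert abs(lo - hi) < 1e-10

    @pytest.mark.parametrize("variant,vals", [
        (Variant.AE, {"sigmaA2": 0.4}),
        (Variant.COHAB_AE, {"lamA": 0.04, "nuA": 0.01}),
        (Variant.COHAB_ACE, {"lamA": 0.04, "nuA": 0.01, "lamC": 0.03, "nuC": 0.005}),
        (Variant.COHAB_CE_PLUS_A, {"sigmaA2": 0.13, **CE_VALUES}),
    ])
    def test_spouse_genetic_contribution_is_zero(self, variant, vals):
        # a spouse pair's covariance must carry no genetic term in any variant
        v_sp = cov_pair(30.0, math.inf, 0.0, variant, vals, group="SPOUSE")
        vals_no_a = {**vals, "sigmaA2": 0.0, "lamA": 0.0}
        v_no_a = cov_pair(30.0, math.inf, 0.0, variant, vals_no_a, group="SPOUSE")
        assert v_sp == pytest.approx(v_no_a, abs=1e-12)


def ce_dataset(seed, n=1000):
    cfg = lifespan_pairs_cohort(n, DEFAULT_CE_PARAMS, seed=seed)
    pheno, pairs, _ = generate_cohort(cfg)
    return FamilyDataset.from_frames(pheno, pairs, value_col="phenotype")


class TestVarianceFits:
    def test_ce_recovery_within_wald_band(self):
        ds = ce_dataset(seed=21, n=1500)
        fit = fit_variance_model(VarianceModelSpec(Variant.COHAB_CE), ds, seed=21,
                                 n_starts=2)
        for name, truth in (("betaC_MZ", 1.41), ("lamC", 0.03)):
            se = fit.standard_errors[name]
            assert abs(fit.estimates[name] - truth) < 4 * se, name
        assert fit.extras["derived"]["mz_dzsib_ratio"] == fit.estimates["betaC_MZ"]

    def test_ae_recovery_of_heritability(self):
        cfg = lifespan_pairs_cohort(1500, DEFAULT_AE_PARAMS, seed=22)
        pheno, pairs, _ = generate_cohort(cfg)
        ds = FamilyDataset.from_frames(pheno, pairs, value_col="phenotype")
        fit = fit_variance_model(VarianceModelSpec(Variant.AE), ds, seed=22, n_starts=2)
        h2 = fit.extras["derived"]["genetic_share"]
        assert abs(h2 - 0.52) < 0.05

    def test_ce_plus_a_nests_ce(self):
        ds = ce_dataset(seed=23, n=600)
        ce = fit_variance_model(VarianceModelSpec(Variant.COHAB_CE), ds, seed=23,
                                n_starts=2, compute_se=False)
        cea = fit_variance_model(VarianceModelSpec(Variant.COHAB_CE_PLUS_A), ds,
                                 seed=23, n_starts=2, compute_se=False)
        assert cea.loglik >= ce.loglik - 1e-6

    def test_loglik_finite_at_optimum_means_all_families_psd(self):
        # -inf would signal a non-PD family covariance at the fitted point
        ds = ce_dataset(seed=24, n=400)
        fit = fit_variance_model(VarianceModelSpec(Variant.COHAB_CE), ds, seed=24,
                                 n_starts=1, compute_se=False)
        assert np.isfinite(fit.loglik) and fit.converged

    def test_ce_without_mz_pairs_refused(self):
        cfg = lifespan_pairs_cohort(50, DEFAULT_CE_PARAMS, seed=25,
                                    relationships=("DZ", "SIB", "SPOUSE"))
        pheno, pairs, _ = generate_cohort(cfg)
        ds = FamilyDataset.from_frames(pheno, pairs, value_col="phenotype")
        with pytest.raises(ValueError, match="requires MZ"):
            fit_variance_model(VarianceModelSpec(Variant.COHAB_CE), ds)


def dummy_fit(loglik, k, variant, fp="fp"):
    f = FitResult(loglik, k, {}, {}, {}, True)
    f.extras["variant"] = variant
    f.extras["data_fingerprint"] = fp
    return f


class TestComparison:
    def test_aic_ranking_arithmetic(self):
        table = compare_variants([dummy_fit(-100.0, 3, "A"), dummy_fit(-99.0, 5, "B")])
        assert table.iloc[0]["variant"] == "A"
        assert table.iloc[0]["aic"] == 206.0
        assert table.iloc[1]["aic"] == 208.0
        assert table.iloc[1]["delta_aic"] == 2.0

    def test_tie_broken_by_fewer_parameters(self):
        table = compare_variants([dummy_fit(-101.0, 4, "BIG"), dummy_fit(-102.0, 3, "SMALL")])
        assert table.iloc[0]["aic"] == table.iloc[1]["aic"]
        assert table.iloc[0]["variant"] == "SMALL"

    def test_mismatched_data_refused(self):
        with pytest.raises(ValueError, match="identical data"):
            compare_variants([dummy_fit(-1.0, 1, "A", fp="x"), dummy_fit(-1.0, 1, "B", fp="y")])

    def test_nested_lrt_column(self):
        ce = dummy_fit(-100.0, 4, "COHAB_CE")
        cea = dummy_fit(-99.0, 5, "COHAB_CE_PLUS_A")
        table = compare_variants([ce, cea], nestings=[("COHAB_CE", "COHAB_CE_PLUS_A", 1)])
        p = table.set_index("variant").loc["COHAB_CE_PLUS_A", "lrt_p_vs_null"]
        assert 0.0 < p < 1.0


class TestProportionCurves:
    def fit_like(self, estimates, variant):
        f = FitResult(0.0, len(estimates), estimates, {}, {}, True)
        f.extras["variant"] = variant.value
        return f

    def test_ce_share_arithmetic_at_18(self):
        est = {"betaC_MZ": 1.41, "betaC_PO": 0.5, "lamC": 0.03, "nuC": 0.0, "var_S": 1.0}
        fit = self.fit_like(est, Variant.COHAB_CE)
        curves = variance_proportion_curves(fit, VarianceModelSpec(Variant.COHAB_CE), [18.0])
        mz = curves[(curves["group"] == "MZ") & (curves["age"] == 18.0)].iloc[0]
        expected_c = 1.41 * (1 - math.exp(-0.03 * 18.0))
        assert mz["C"] == pytest.approx(expected_c, abs=1e-10)
        assert mz["E"] == pytest.approx(1 - expected_c, abs=1e-10)
        assert mz["A"] == 0.0

    def test_ae_share_constant_in_age(self):
        est = {"sigmaA2": 0.52, "var_S": 1.0}
        fit = self.fit_like(est, Variant.AE)
        curves = variance_proportion_curves(fit, VarianceModelSpec(Variant.AE),
                                            [0.0, 30.0, 80.0])
        mz = curves[curves["group"] == "MZ"]
        assert np.allclose(mz["A"], 0.52)

    def test_shares_at_birth_reduce_to_constant_genetic_term(self):
        est = {"sigmaA2": 0.13, "betaC_MZ": 1.41, "betaC_PO": 0.5,
               "lamC": 0.03, "nuC": 0.005, "var_S": 1.0}
        fit = self.fit_like(est, Variant.COHAB_CE_PLUS_A)
        curves = variance_proportion_curves(
            fit, VarianceModelSpec(Variant.COHAB_CE_PLUS_A), [0.0])
        mz = curves[curves["group"] == "MZ"].iloc[0]
        assert mz["A"] == pytest.approx(0.13, abs=1e-12)
        assert mz["C"] == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_reference_variance_refused(self):
        fit = self.fit_like({"sigmaA2": 0.5, "var_S": 1.0}, Variant.AE)
        with pytest.raises(ValueError, match="positive"):
            variance_proportion_curves(fit, VarianceModelSpec(Variant.AE), [10.0],
                                       ref_var=-1.0)
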