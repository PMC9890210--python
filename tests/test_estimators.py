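"""Estimator correctness: bivariate-normal kernel closed forms, bivariate
probit vs single-equation probit, G-computation oracles, PSM and
meta-learner behaviour, subgroup interaction calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

import statsmodels.api as sm

from trialemu.config import SimConfig, paper_like_config
from trialemu.estimators import (
    biprobit_iv_ate,
    build_design,
    bvn_cdf,
    metalearner_ate,
    psm_ate,
    regression_adjustment_ate,
    subgroup_ates,
)
from trialemu.synthetic import core_analysis_cohort, oracle_true_ate


def randomized_config(n=10_000, seed=5, **kw):
    """Treatment independent of covariates and frailty (a randomized trial)."""
    return SimConfig(
        n_patients=n,
        seed=seed,
        instrument_strength=0.0,
        confounding_strength=0.0,
        simple_pci_frac=0.0,
        treatment_model_coefs={"intercept": 0.0},
        **kw,
    )


def probit_process_cohort(n, seed, rho, beta=-0.4):
    """Data drawn exactly from the recursive bivariate probit model."""
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    x = rng.normal(size=n)
    u = rng.normal(size=n)
    v = rho * u + math.sqrt(1 - rho**2) * rng.normal(size=n)
    t = (0.8 * z + 0.3 * x + u > 0).astype(int)
    y = (0.2 + beta * t + 0.5 * x + v > 0).astype(int)
    return pd.DataFrame(
        {"instrument": z, "x": x, "treatment": t, "composite_event": y}
    )


class TestBvnCdf:
    @pytest.mark.parametrize("rho", np.round(np.arange(-0.9, 0.91, 0.3), 10).tolist())
    def test_closed_form_at_origin(self, rho):
        expected = 0.25 + math.asin(rho) / (2 * math.pi)
        assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-8)

    def test_independence_factorizes(self):
        for a, b in [(-1.3, 0.4), (0.0, 2.0), (1.1, -0.7)]:
            assert bvn_cdf(a, b, 0.0) == pytest.approx(norm.cdf(a) * norm.cdf(b), abs=1e-10)

    def test_marginalization_at_infinity(self):
        assert bvn_cdf(0.7, np.inf, 0.5) == pytest.approx(norm.cdf(0.7), abs=1e-10)
        assert bvn_cdf(-np.inf, 0.7, 0.5) == 0.0

    def test_against_scipy_oracle(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.normal(0, 2, size=2)
            rho = rng.uniform(-0.99, 0.99)
            ref = multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf([a, b])
            assert bvn_cdf(a, b, rho) == pytest.approx(ref, abs=1e-8)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.3, 0.8, 1.0) == pytest.approx(norm.cdf(0.3), abs=1e-12)
        assert bvn_cdf(0.3, -0.3, -1.0) == pytest.approx(
            max(norm.cdf(0.3) + norm.cdf(-0.3) - 1, 0.0), abs=1e-12
        )
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.5)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(-5, 5),
        rho=st.floats(-0.95, 0.95),
    )
    def test_probability_properties(self, a, b, rho):
        p = bvn_cdf(a, b, rho)
        assert 0.0 <= p <= 1.0
        assert p <= min(norm.cdf(a), norm.cdf(b)) + 1e-12
        # symmetry in the arguments
        assert p == pytest.approx(bvn_cdf(b, a, rho), abs=1e-12)
        # monotone in each argument
        assert p <= bvn_cdf(a + 0.5, b, rho) + 1e-12


class TestBiprobit:
    def test_rho_zero_matches_single_equation_probit(self):
        # data from the bivariate probit's own process with independent
        # errors: the outcome equation collapses to an ordinary probit and
        # the treatment coefficients must agree (nested-model equivalence)
        coh = probit_process_cohort(n=20_000, seed=50, rho=0.0)
        est, fit = biprobit_iv_ate(coh, covariates=["x"], bootstrap=0)
        X, data = build_design(coh, ["x"])
        Xy = sm.add_constant(
            np.column_stack([data["treatment"].to_numpy(float), X.to_numpy(float)]),
            has_constant="add",
        )
        probit = sm.Probit(data["composite_event"].to_numpy(float), Xy).fit(disp=0)
        beta_prob, se_prob = probit.params[1], probit.bse[1]
        beta_biv = fit.outcome_coefs[1]
        assert abs(beta_biv - beta_prob) < 3 * math.sqrt(2) * se_prob
        assert abs(fit.rho) < 0.15

    def test_recovers_rho_and_effect_under_confounded_probit_process(self):
        # correlated errors: the MLE should separate the structural effect
        # from the confounding correlation
        coh = probit_process_cohort(n=20_000, seed=51, rho=0.5, beta=-0.4)
        est, fit = biprobit_iv_ate(coh, covariates=["x"], bootstrap=0)
        assert fit.rho == pytest.approx(0.5, abs=0.12)
        assert fit.outcome_coefs[1] == pytest.approx(-0.4, abs=0.1)

    def test_constant_instrument_raises(self):
        coh = core_analysis_cohort(randomized_config(n=2000))
        coh["instrument"] = 0.5
        with pytest.raises(ValueError, match="instrument is constant"):
            biprobit_iv_ate(coh, bootstrap=0)

    def test_ci_brackets_point_and_is_seeded(self):
        coh = core_analysis_cohort(paper_like_config(n_patients=2000, seed=51))
        covs = ["age", "ckd"]
        e1, _ = biprobit_iv_ate(coh, covariates=covs, bootstrap=25, seed=9)
        e2, _ = biprobit_iv_ate(coh, covariates=covs, bootstrap=25, seed=9)
        assert e1.ci_low <= e1.ate <= e1.ci_high
        assert (e1.ate, e1.ci_low, e1.ci_high) == (e2.ate, e2.ci_low, e2.ci_high)
        assert -1 <= e1.ate <= 1


class TestRegressionAdjustment:
    def test_zero_fitted_treatment_coefficient_gives_zero_ate(self):
        # equal event rates in both arms: the fitted treatment coefficient
        # is zero, so G-computation returns exactly zero
        rows = (
            [{"treatment": 0, "composite_event": 1}] * 50
            + [{"treatment": 0, "composite_event": 0}] * 50
            + [{"treatment": 1, "composite_event": 1}] * 30
            + [{"treatment": 1, "composite_event": 0}] * 30
        )
        df = pd.DataFrame(rows)
        df["age"] = 70.0
        est = regression_adjustment_ate(df, ["age"], bootstrap=0)
        assert est.ate == pytest.approx(0.0, abs=1e-8)

    def test_matches_explicit_counterfactual_averaging(self):
        rng = np.random.default_rng(12)
        n = 2000
        x = rng.binomial(1, 0.4, n)
        t = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, norm.cdf(-0.3 + 0.8 * x - 0.5 * t))
        df = pd.DataFrame({"x": x, "treatment": t, "composite_event": y})
        est = regression_adjustment_ate(df, ["x"], bootstrap=0)
        # independent G-computation from a probit fit on the same data
        X = sm.add_constant(np.column_stack([t, x]).astype(float), has_constant="add")
        b = sm.Probit(y.astype(float), X).fit(disp=0).params
        oracle = np.mean(norm.cdf(b[0] + b[1] + b[2] * x) - norm.cdf(b[0] + b[2] * x))
        assert est.ate == pytest.approx(oracle, abs=1e-6)

    def test_randomized_data_recovers_oracle(self):
        cfg = randomized_config(n=6000, seed=13)
        est = regression_adjustment_ate(
            core_analysis_cohort(cfg), bootstrap=40, ci_method="bootstrap_normal", seed=1
        )
        oracle = oracle_true_ate(cfg, 100_000)
        se_boot = (est.ci_high - est.ci_low) / (2 * 1.959964)
        assert abs(est.ate - oracle.ate) < 3 * math.sqrt(se_boot**2 + oracle.se**2)


class TestPSM:
    def test_constant_covariates_equal_arm_sizes_recover_raw_difference(self):
        rng = np.random.default_rng(3)
        n = 100
        df = pd.DataFrame(
            {
                "treatment": np.r_[np.ones(50), np.zeros(50)],
                "composite_event": rng.binomial(1, np.r_[np.full(50, 0.4), np.full(50, 0.7)]),
                "age": 70.0,
            }
        )
        est = psm_ate(df, ["age"], bootstrap=0, seed=2)
        raw = (
            df.loc[df.treatment == 1, "composite_event"].mean()
            - df.loc[df.treatment == 0, "composite_event"].mean()
        )
        assert est.ate == pytest.approx(raw, abs=1e-12)
        assert est.notes["n_pairs"] == 50

    def test_reduces_measured_confounding_bias(self):
        cfg = paper_like_config(n_patients=6000, seed=52).with_(confounding_strength=0.0)
        coh = core_analysis_cohort(cfg)
        oracle = oracle_true_ate(cfg, 100_000)
        naive = (
            coh.loc[coh.treatment == 1, "composite_event"].mean()
            - coh.loc[coh.treatment == 0, "composite_event"].mean()
        )
        est = psm_ate(coh, bootstrap=0, seed=2)
        assert abs(est.ate - oracle.ate) < abs(naive - oracle.ate)

    def test_deterministic_given_seed(self):
        coh = core_analysis_cohort(randomized_config(n=1500, seed=53))
        e1 = psm_ate(coh, ["age", "ckd"], bootstrap=10, seed=4)
        e2 = psm_ate(coh, ["age", "ckd"], bootstrap=10, seed=4)
        assert (e1.ate, e1.ci_low, e1.ci_high) == (e2.ate, e2.ci_low, e2.ci_high)


class TestMetaLearners:
    @pytest.mark.parametrize("kind", ["S", "T", "X"])
    def test_constant_outcome_gives_zero(self, kind):
        coh = core_analysis_cohort(randomized_config(n=800, seed=54))
        coh["composite_event"] = 1
        est = metalearner_ate(coh, ["age", "ckd"], kind=kind, bootstrap=0, seed=1)
        assert est.ate == pytest.approx(0.0, abs=1e-6)

    def test_s_and_t_agree_without_effect_modification(self):
        cfg = randomized_config(n=8000, seed=55)
        cfg.outcome_model.covariate_loghr = {}
        coh = core_analysis_cohort(cfg)
        kw = dict(bootstrap=25, ci_method="bootstrap_normal")
        s = metalearner_ate(coh, ["age", "diabetes"], kind="S", seed=1, **kw)
        t = metalearner_ate(coh, ["age", "diabetes"], kind="T", seed=1, **kw)
        se_s = (s.ci_high - s.ci_low) / (2 * 1.959964)
        se_t = (t.ci_high - t.ci_low) / (2 * 1.959964)
        assert abs(s.ate - t.ate) < 3 * math.sqrt(se_s**2 + se_t**2)

    def test_empty_arm_raises(self):
        coh = core_analysis_cohort(randomized_config(n=500, seed=56))
        coh["treatment"] = 1
        with pytest.raises(ValueError, match="non-empty"):
            metalearner_ate(coh, ["age"], kind="T", bootstrap=0)

    def test_records_base_learner_config(self):
        coh = core_analysis_cohort(randomized_config(n=800, seed=57))
        est = metalearner_ate(
            coh, ["age"], kind="S", base_learner_config={"max_depth": 2}, bootstrap=0
        )
        assert est.notes["base_learner"]["max_depth"] == 2


class TestSubgroups:
    def test_identical_strata_get_identical_ates(self):
        coh = core_analysis_cohort(randomized_config(n=1500, seed=58))
        doubled = pd.concat(
            [coh.assign(grp=0), coh.assign(grp=1)], ignore_index=True
        )
        tab = subgroup_ates(doubled, ["grp"], ["age", "ckd"], bootstrap=0)
        ates = tab["ate"].to_numpy()
        assert ates[0] == pytest.approx(ates[1], abs=1e-10)

    def test_single_arm_stratum_flagged(self):
        coh = core_analysis_cohort(randomized_config(n=1000, seed=59))
        coh.loc[coh["male"] == 0, "treatment"] = 1
        tab = subgroup_ates(coh, ["male"], ["age"], bootstrap=0)
        flags = tab.set_index("stratum")["flag"]
        assert flags.loc[0] == "single_arm"
        assert np.isnan(tab.set_index("stratum")["ate"].loc[0])

    def test_effect_modification_orders_strata(self):
        cfg = randomized_config(n=20_000, seed=60)
        cfg.outcome_model.treatment_loghr_modifiers = {"male": -1.0}
        coh = core_analysis_cohort(cfg)
        tab = subgroup_ates(coh, ["male"], ["age"], bootstrap=0).set_index("stratum")
        # more protective log-HR for males: larger risk reduction
        assert tab.loc[1, "ate"] < tab.loc[0, "ate"]

    def test_null_interaction_p_calibrated(self):
        hits = 0
        reps = 150
        for rep in range(reps):
            coh = core_analysis_cohort(randomized_config(n=700, seed=3000 + rep))
            tab = subgroup_ates(coh, ["diabetes"], ["age"], bootstrap=0)
            if tab["p_interaction"].iloc[0] < 0.05:
                hits += 1
        assert 0.005 <= hits / reps <= 0.11
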