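import warnings

import numpy as np
import pandas as pd
import pytest

from pvsquant import (
    CohortSpec,
    CollinearityError,
    ParameterError,
    age_equivalent_years,
    decompose_within_between,
    fit_baseline_model,
    fit_medication_model,
    fit_treatment_model,
    pairwise_contrasts,
    simulate_cohort,
)
from pvsquant.stats import BASELINE_PREDICTORS, bonferroni, fit_adjusted_model


@pytest.fixture(scope="module")
def cohort_and_fit():
    df = simulate_cohort(CohortSpec(n_per_arm=200, seed=3))
    return df, fit_treatment_model(df)


# ---------------------------------------------------------------------------
# Baseline OLS
# ---------------------------------------------------------------------------

def _baseline_frame(n=120, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "male": rng.integers(0, 2, n),
        "bpf": rng.normal(0.82, 0.04, n),
        "age": rng.normal(68, 8, n),
        "cvd": rng.integers(0, 2, n),
        "baseline_sbp": rng.normal(138, 16, n),
        "ckd": rng.integers(0, 2, n),
        "black": rng.integers(0, 2, n),
        "logwmh": rng.normal(0.002, 0.001, n),
        "site": rng.integers(0, 4, n),
        "timepoint": 0,
    })
    coefs = {"male": 0.081, "bpf": -1.9, "age": 0.004, "cvd": 0.067,
             "baseline_sbp": 0.00025, "ckd": -0.021, "black": -0.065,
             "logwmh": -1.05}
    site_eff = np.array([0.0, 0.05, -0.03, 0.02])
    y = 1.23 + site_eff[df["site"]]
    for k, b in coefs.items():
        y = y + b * df[k]
    df["pvs_volume_fraction"] = y + rng.normal(0, noise, n)
    return df, coefs


def test_baseline_ols_recovers_noise_free_coefficients():
    df, coefs = _baseline_frame()
    fit = fit_baseline_model(df)
    for k, b in coefs.items():
        assert fit.params[k] == pytest.approx(b, abs=1e-8)
    assert fit.kind == "ols"
    assert fit.n_obs == len(df)


def test_baseline_standardized_beta_formula():
    df, _ = _baseline_frame(noise=0.05)
    fit = fit_baseline_model(df)
    sd_y = df["pvs_volume_fraction"].std(ddof=1)
    for p in BASELINE_PREDICTORS:
        expect = fit.params[p] * df[p].std(ddof=1) / sd_y
        assert fit.std_beta[p] == pytest.approx(expect, rel=1e-10)


def test_baseline_collinearity_named():
    df, _ = _baseline_frame()
    df["black"] = df["ckd"]
    with pytest.raises(CollinearityError):
        fit_baseline_model(df)


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def test_model1_recovers_interaction(cohort_and_fit):
    df, fit = cohort_and_fit
    term = fit.interaction
    assert term["ci_low"] <= -0.029 <= term["ci_high"]
    assert term["estimate"] < 0
    assert fit.n_participants == 400
    assert fit.n_obs == 800
    # variance components near their simulated values
    assert 0.02 < fit.vc["participant"] < 0.12     # true 0.0625
    assert 0.003 < fit.vc["residual"] < 0.013      # true 0.0064


def test_model2_recovers_interaction(cohort_and_fit):
    df, _ = cohort_and_fit
    fit = fit_adjusted_model(df)
    term = fit.interaction
    assert term["ci_low"] <= -0.029 <= term["ci_high"]
    for name in ("logwmh_between", "logwmh_within",
                 "tbv_between", "tbv_within"):
        assert name in fit.params.index


def test_model3_recovers_ccb_interaction():
    spec = CohortSpec(n_per_arm=200, seed=12,
                      med_time_effects={"acei_arb": 0.0, "beta_blocker": 0.0,
                                        "ccb": -0.038, "diuretic": 0.0})
    df = simulate_cohort(spec)
    fit = fit_medication_model(df)
    term = fit.term("exp_ccb:timepoint")
    assert term["ci_low"] <= -0.038 <= term["ci_high"]


def test_model3_drops_zero_variance_class():
    spec = CohortSpec(n_per_arm=40, seed=1)
    spec.med_beta["beta_blocker"] = None
    df = simulate_cohort(spec)
    with pytest.warns(UserWarning, match="beta_blocker"):
        fit = fit_medication_model(df)
    assert "exp_beta_blocker" not in fit.params.index
    assert "exp_ccb" in fit.params.index


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def test_pairwise_contrast_linear_algebra_oracle(cohort_and_fit):
    _, fit = cohort_and_fit
    pw = pairwise_contrasts(fit)
    assert pw.m == 4
    est = pw.estimates
    p = fit.params
    assert est["within_intensive"]["estimate"] == pytest.approx(
        p["timepoint"] + p["arm:timepoint"], rel=1e-12)
    assert est["within_standard"]["estimate"] == pytest.approx(
        p["timepoint"], rel=1e-12)
    assert est["between_baseline"]["estimate"] == pytest.approx(
        p["arm"], rel=1e-12)
    assert est["between_followup"]["estimate"] == pytest.approx(
        p["arm"] + p["arm:timepoint"], rel=1e-12)
    # SE of a sum from the coefficient covariance
    cov = fit.cov_params
    var = (cov.loc["timepoint", "timepoint"]
           + cov.loc["arm:timepoint", "arm:timepoint"]
           + 2 * cov.loc["timepoint", "arm:timepoint"])
    assert est["within_intensive"]["se"] == pytest.approx(np.sqrt(var),
                                                          rel=1e-10)
    for term in est.values():
        assert term["p_adj"] == pytest.approx(min(1.0, 4 * term["p_raw"]))
        half = term["ci_high"] - term["estimate"]
        assert half == pytest.approx(1.959963984540054 * term["se"],
                                     rel=1e-9)


def test_bonferroni():
    assert bonferroni(0.01, 4) == pytest.approx(0.04)
    assert bonferroni(0.5, 4) == 1.0
    with pytest.raises(ParameterError):
        bonferroni(0.1, 0)


# ---------------------------------------------------------------------------
# Within/between decomposition
# ---------------------------------------------------------------------------

def test_decompose_within_between_oracle():
    df = pd.DataFrame({
        "participant": [1, 1, 2, 2],
        "timepoint": [0, 1, 0, 1],
        "x": [2.0, 4.0, 10.0, 10.0],
    })
    out = decompose_within_between(df, "x")
    np.testing.assert_allclose(out["x_between"], [3.0, 3.0, 10.0, 10.0])
    np.testing.assert_allclose(out["x_within"], [-1.0, 1.0, 0.0, 0.0])
    np.testing.assert_allclose(out["x_between"] + out["x_within"], out["x"])


def test_decompose_single_visit_warns_and_too_many_rows_raise():
    df = pd.DataFrame({"participant": [1, 1, 2], "timepoint": [0, 1, 0],
                       "x": [1.0, 3.0, 5.0]})
    with pytest.warns(UserWarning, match="single-visit"):
        out = decompose_within_between(df, "x")
    assert out.loc[2, "x_within"] == 0.0
    bad = pd.DataFrame({"participant": [1, 1, 1],
                        "timepoint": [0, 1, 2], "x": [1.0, 2.0, 3.0]})
    with pytest.raises(ParameterError):
        decompose_within_between(bad, "x")


# ---------------------------------------------------------------------------
# Age equivalence
# ---------------------------------------------------------------------------

def test_age_equivalent_years():
    assert age_equivalent_years(-0.027, 0.004) == pytest.approx(6.75,
                                                                abs=1e-12)
    assert age_equivalent_years(0.008, -0.004) == pytest.approx(2.0)
    with pytest.raises(ParameterError):
        age_equivalent_years(0.01, 0.0)
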