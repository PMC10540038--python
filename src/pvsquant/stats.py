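"""Baseline regression and longitudinal mixed-effects models.

The battery mirrors a two-arm longitudinal imaging analysis:

* a baseline multiple linear regression of PVS volume fraction on
  demographics, vascular risk factors, logWMH and BPF, adjusted for MRI
  site (fixed site indicators), with standardized coefficients;
* Model 1 — linear mixed model with random intercepts for participant and
  site; fixed effects timepoint (0/1), treatment group, group-by-time (the
  headline coefficient: relative change in PVS volume fraction, in
  percentage points over the follow-up interval), age, sex, race, CVD, CKD,
  baseline SBP, logWMH; REML estimation;
* Model 2 — Model 1 plus within/between decompositions of logWMH and total
  brain volume, to check that the treatment effect is not driven by WMH or
  atrophy changes;
* Model 3 — class-exposure model: main effects and exposure-by-time
  interactions for the four antihypertensive classes, plus covariates
  including achieved SBP;
* Bonferroni-corrected pairwise contrasts (within-arm changes and
  between-arm differences at each timepoint);
* the age-equivalence arithmetic translating a within-arm change into years
  of age-related PVS enlargement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import (
    CollinearityError,
    ConvergenceError,
    ParameterError,
)
from .measures import MED_CLASSES

#: Model 1 fixed-effect covariates beyond the treatment terms.
BASE_COVARIATES = ("age", "male", "black", "cvd", "ckd",
                   "baseline_sbp", "logwmh")

#: Baseline-model predictors (site indicators are added on top).
BASELINE_PREDICTORS = ("male", "bpf", "age", "cvd", "baseline_sbp",
                       "ckd", "black", "logwmh")


@dataclass
class ModelFit:
    """A fitted model: fixed effects, their covariance, variance components."""

    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame           # columns: low, high
    pvalues: pd.Series
    cov_params: pd.DataFrame
    vc: dict = field(default_factory=dict)   # participant/site/residual vars
    std_beta: pd.Series | None = None
    n_obs: int = 0
    n_participants: int = 0
    converged: bool = True
    kind: str = "mixed"

    def term(self, name: str) -> dict:
        return {
            "estimate": float(self.params[name]),
            "se": float(self.bse[name]),
            "ci_low": float(self.conf_int.loc[name, "low"]),
            "ci_high": float(self.conf_int.loc[name, "high"]),
            "p": float(self.pvalues[name]),
        }

    @property
    def interaction(self) -> dict:
        """The headline group-by-time coefficient (Models 1 and 2)."""
        return self.term("arm:timepoint")


@dataclass
class PairwiseResult:
    """Within-arm changes and between-arm differences with Bonferroni."""

    estimates: dict                 # name -> term dict with p_raw/p_adj
    m: int


# ---------------------------------------------------------------------------
# Baseline OLS
# ---------------------------------------------------------------------------

def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name a column whose removal restores full rank
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=[col]).values) == rank:
                raise CollinearityError(f"design is rank deficient: {col!r}")
        raise CollinearityError("design is rank deficient")


def fit_baseline_model(df: pd.DataFrame,
                       outcome: str = "pvs_volume_fraction",
                       predictors: tuple[str, ...] = BASELINE_PREDICTORS,
                       site_col: str = "site") -> ModelFit:
    """OLS of baseline PVS volume fraction on predictors, adjusted for site.

    Uses baseline rows only (timepoint == 0 when present). Standardized
    coefficients are b * SD(x) / SD(y).
    """
    data = df[df["timepoint"] == 0] if "timepoint" in df.columns else df
    data = data.dropna(subset=[outcome, *predictors])
    y = data[outcome].astype(float)
    X = data[list(predictors)].astype(float).copy()
    sites = pd.get_dummies(data[site_col], prefix="site",
                           drop_first=True, dtype=float)
    X = pd.concat([X, sites], axis=1)
    X = sm.add_constant(X)
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int()
    ci.columns = ["low", "high"]
    sd_y = y.std(ddof=1)
    std_beta = pd.Series(
        {p: res.params[p] * data[p].astype(float).std(ddof=1) / sd_y
         for p in predictors})
    return ModelFit(
        params=res.params, bse=res.bse, conf_int=ci, pvalues=res.pvalues,
        cov_params=res.cov_params(), std_beta=std_beta,
        n_obs=int(res.nobs), n_participants=int(res.nobs),
        converged=True, kind="ols",
    )


# ---------------------------------------------------------------------------
# Mixed models
# ---------------------------------------------------------------------------

def _fit_mixed(df: pd.DataFrame, fixed: list[str],
               outcome: str = "pvs_volume_fraction") -> ModelFit:
    """REML linear mixed model: site random intercept (grouping factor) plus
    participant random intercept (variance component nested in site)."""
    cols = sorted({c.split(":")[0] for t in fixed for c in t.split(":")})
    data = df.dropna(subset=[outcome, *cols, "site", "participant"]).copy()
    formula = f"{outcome} ~ " + " + ".join(fixed)
    md = sm.MixedLM.from_formula(
        formula, data=data, groups="site", re_formula="1",
        vc_formula={"participant": "0 + C(participant)"},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = md.fit(reml=True, method="lbfgs", maxiter=200)
        if not res.converged:
            res = md.fit(reml=True, method="powell", maxiter=500)
    if not res.converged:
        raise ConvergenceError("mixed model failed to converge")
    k = len(res.fe_params)
    names = res.fe_params.index
    bse = res.bse[:k]
    bse.index = names
    pv = res.pvalues[:k]
    pv.index = names
    ci = res.conf_int().iloc[:k]
    ci.columns = ["low", "high"]
    ci.index = names
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                       index=names, columns=names)
    vc = {
        "site": float(np.asarray(res.cov_re)[0, 0]),
        "participant": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
        "residual": float(res.scale),
    }
    return ModelFit(
        params=res.fe_params, bse=bse, conf_int=ci, pvalues=pv,
        cov_params=cov, vc=vc,
        n_obs=len(data), n_participants=data["participant"].nunique(),
        converged=bool(res.converged), kind="mixed",
    )


def fit_treatment_model(df: pd.DataFrame) -> ModelFit:
    """Model 1: treatment effect on PVS volume fraction.

    The ``arm:timepoint`` coefficient is the relative change between arms
    over the follow-up interval.
    """
    fixed = ["timepoint", "arm", "arm:timepoint", *BASE_COVARIATES]
    return _fit_mixed(df, fixed)


def decompose_within_between(df: pd.DataFrame, variable: str
                             ) -> pd.DataFrame:
    """Split a time-varying covariate into participant mean and deviation.

    Adds ``{variable}_between`` (constant within participant) and
    ``{variable}_within`` (sums to zero within participant). Participants
    with a single visit get within = 0 and between = the observed value.
    """
    if df.groupby("participant")["timepoint"].count().max() > 2:
        raise ParameterError("expected at most 2 rows per participant")
    out = df.copy()
    grp = out.groupby("participant")[variable]
    between = grp.transform("mean")
    out[f"{variable}_between"] = between
    out[f"{variable}_within"] = out[variable] - between
    n_single = int((grp.transform("count") == 1).sum())
    if n_single:
        warnings.warn(f"{n_single} single-visit rows: within-effect set to 0",
                      stacklevel=2)
    return out


def fit_adjusted_model(df: pd.DataFrame) -> ModelFit:
    """Model 2: Model 1 plus within/between logWMH and TBV adjustment."""
    data = decompose_within_between(df, "logwmh")
    data = decompose_within_between(data, "tbv")
    fixed = ["timepoint", "arm", "arm:timepoint",
             "age", "male", "black", "cvd", "ckd", "baseline_sbp",
             "logwmh_between", "logwmh_within", "tbv_between", "tbv_within"]
    return _fit_mixed(data, fixed)


def fit_medication_model(df: pd.DataFrame) -> ModelFit:
    """Model 3: antihypertensive class exposures and their time interactions.

    Classes with zero exposure variance are dropped with a warning naming
    the class.
    """
    fixed = ["timepoint", "arm", "age", "male", "black", "cvd", "ckd",
             "baseline_sbp", "achieved_sbp", "logwmh", "tbv"]
    for c in MED_CLASSES:
        col = f"exp_{c}"
        if df[col].std(ddof=0) == 0:
            warnings.warn(f"dropping {c}: zero exposure variance",
                          stacklevel=2)
            continue
        fixed += [col, f"{col}:timepoint"]
    return _fit_mixed(df, fixed)


# ---------------------------------------------------------------------------
# Contrasts and derived arithmetic
# ---------------------------------------------------------------------------

def bonferroni(p_raw: float, m: int) -> float:
    """min(1, m * p); m is the family size."""
    if m < 1:
        raise ParameterError("family size m must be >= 1")
    return min(1.0, m * p_raw)


def _contrast(fit: ModelFit, weights: dict[str, float], m: int) -> dict:
    c = pd.Series(0.0, index=fit.params.index)
    for k, w in weights.items():
        c[k] = w
    est = float(c @ fit.params)
    se = float(np.sqrt(c @ fit.cov_params @ c))
    z = est / se if se > 0 else np.inf * np.sign(est)
    p = 2 * sps.norm.sf(abs(z))
    return {
        "estimate": est, "se": se,
        "ci_low": est - 1.959963984540054 * se,
        "ci_high": est + 1.959963984540054 * se,
        "p_raw": float(p), "p_adj": bonferroni(float(p), m),
    }


def pairwise_contrasts(fit: ModelFit, m: int = 4) -> PairwiseResult:
    """Within-arm changes and between-arm differences, Bonferroni-adjusted.

    Family (m = 4 by default): intensive within-arm change (time +
    interaction), standard within-arm change (time), between-arm difference
    at follow-up (group + interaction) and at baseline (group).
    """
    if m < 1:
        raise ParameterError("family size m must be >= 1")
    if not fit.converged:
        raise ConvergenceError("cannot form contrasts on a non-converged fit")
    res = {
        "within_intensive": _contrast(
            fit, {"timepoint": 1.0, "arm:timepoint": 1.0}, m),
        "within_standard": _contrast(fit, {"timepoint": 1.0}, m),
        "between_followup": _contrast(
            fit, {"arm": 1.0, "arm:timepoint": 1.0}, m),
        "between_baseline": _contrast(fit, {"arm": 1.0}, m),
    }
    return PairwiseResult(estimates=res, m=m)


def age_equivalent_years(delta_fraction: float, age_coef: float) -> float:
    """Years of age-related PVS change equivalent to a fraction change.

    Returns |delta_fraction / age_coef|: the magnitude, in years, of the
    age-related enlargement that the observed change offsets (a negative
    change against a positive age slope is a reversal).
    """
    if age_coef == 0:
        raise ParameterError("age coefficient must be nonzero")
    return abs(delta_fraction / age_coef)
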