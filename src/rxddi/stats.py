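"""Two-stage statistical comparison of the DDI and non-DDI groups.

Stage one screens each candidate variable with a univariate test -- Pearson's
chi-squared (uncorrected) for categoricals, Welch's t-test for continuous
variables -- against a Bonferroni-corrected threshold alpha / n_tests
(0.05 / 34 = 1.47e-3 by default).  Stage two fits one multivariable logistic
model per screened predictor: predictor + a fixed adjustment block (sex, age
at first citalopram prescription, duration of the longest citalopram window,
Townsend deprivation, qualifications, BMI, ethnicity, ever smoked), reporting
odds ratios with Wald 95% CIs on the log-odds scale.

A separate linear model relates the longest co-prescription overlap (days) to
CYP2C19 metaboliser phenotype (normal metabolisers as reference) with the same
adjustment block minus the citalopram-duration covariate, judged at nominal
alpha = 0.05 as a single pre-specified test.

Sensitivity modes: (a) exclude topical drugs, (b) contraindicated interactions
only -- both re-derive the exposure table through the catalogue filter --
(c) drop the citalopram-duration covariate, (d) replace it with the number of
citalopram prescriptions.

Missing data are handled complete-case per model, with n_used reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .catalog import Catalog
from .episodes import build_cohort

SENSITIVITY_MODES = ("main", "a_exclude_topical", "b_contraindicated_only",
                     "c_drop_duration_covariate", "d_replace_with_n_prescriptions")

_MODE_TO_FILTER = {
    "main": "default",
    "a_exclude_topical": "exclude_topical",
    "b_contraindicated_only": "contraindicated_only",
    "c_drop_duration_covariate": "default",
    "d_replace_with_n_prescriptions": "default",
}

DEFAULT_COVARIATES = (
    "sex", "age_at_first_citalopram", "cital_longest_days", "townsend",
    "qualifications", "bmi", "ethnicity", "ever_smoked",
)
DEFAULT_CATEGORICAL = frozenset({"sex", "qualifications", "ethnicity"})

# |log-odds coefficient| beyond this is treated as (quasi-)separation.
SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the statistical stage; defaults mirror the main analysis."""
    alpha: float = 0.05
    n_tests: int = 34
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    categorical: frozenset[str] = DEFAULT_CATEGORICAL
    mode: str = "main"
    welch: bool = True                  # Welch (unequal-variance) t-test
    duration_log1p: bool = False        # optional log1p transform of overlap days

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if self.mode not in SENSITIVITY_MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def alpha_bonf(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)

    def effective_covariates(self) -> tuple[str, ...]:
        """Adjustment block after applying the (c)/(d) sensitivity edits."""
        covs = list(self.covariates)
        if self.mode == "c_drop_duration_covariate":
            covs = [c for c in covs if c != "cital_longest_days"]
        elif self.mode == "d_replace_with_n_prescriptions":
            covs = ["n_citalopram_rx" if c == "cital_longest_days" else c
                    for c in covs]
        return tuple(covs)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnivariateResult:
    variable: str
    test: str                       # chi_squared | t_test
    statistic: float
    p_value: float
    significant: bool
    group_summaries: dict
    n_missing: dict
    untestable: bool = False


def _categorical_test(series: pd.Series, status: pd.Series):
    table = pd.crosstab(series, status)
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, np.nan, True, table
    # Pearson chi-squared without Yates correction, multi-level supported.
    stat, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), False, table


def _summaries_categorical(table: pd.crosstab) -> dict:
    out = {}
    for grp in table.columns:
        col = table[grp]
        total = int(col.sum())
        out[bool(grp)] = {str(lvl): (int(n), 100.0 * n / total if total else np.nan)
                          for lvl, n in col.items()}
    return out


def univariate_screen(cohort: pd.DataFrame,
                      variables: Mapping[str, str],
                      config: AnalysisConfig = AnalysisConfig()) -> list[UnivariateResult]:
    """Compare each variable between the DDI and non-DDI groups.

    ``variables`` maps column name → 'categorical' | 'continuous'.  Missing
    values are excluded per variable and counted per group.  A variable with a
    single observed level (or an empty group) is returned flagged untestable
    rather than raising.
    """
    alpha_bonf = config.alpha_bonf
    status = cohort["ddi_status"].astype(bool)
    results: list[UnivariateResult] = []
    for name, kind in variables.items():
        col = cohort[name]
        ok = col.notna()
        n_missing = {
            True: int((~ok & status).sum()),
            False: int((~ok & ~status).sum()),
        }
        x, g = col[ok], status[ok]
        if kind == "categorical":
            stat, p, untestable, table = _categorical_test(x, g)
            summaries = _summaries_categorical(table) if not untestable else {}
            test = "chi_squared"
        elif kind == "continuous":
            x = x.astype(float)
            a, b = x[g], x[~g]
            if len(a) < 2 or len(b) < 2 or (x.nunique() < 2):
                stat, p, untestable, summaries = np.nan, np.nan, True, {}
            else:
                res = sps.ttest_ind(a, b, equal_var=not config.welch)
                stat, p, untestable = float(res.statistic), float(res.pvalue), False
                summaries = {
                    grp: {"n": int(len(v)), "mean": float(v.mean()),
                          "sd": float(v.std(ddof=1)), "median": float(v.median())}
                    for grp, v in ((True, a), (False, b))
                }
            test = "t_test"
        else:
            raise ValueError(f"{name}: unknown variable kind {kind!r}")
        results.append(UnivariateResult(
            variable=name, test=test, statistic=stat, p_value=p,
            significant=bool(not untestable and p < alpha_bonf),
            group_summaries=summaries, n_missing=n_missing,
            untestable=untestable))
    return results


# ---------------------------------------------------------------------------
# Multivariable models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    term: str
    estimate: float                 # odds ratio (logistic) or coefficient (linear)
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    flag: str | None = None         # 'separation' | 'untestable' | None


def _term(name: str, categorical: frozenset[str],
          frame: pd.DataFrame, reference: str | None = None) -> str:
    if name in categorical or frame[name].dtype == object:
        if reference is not None:
            return f"C({name}, Treatment('{reference}'))"
        return f"C({name})"
    return name


def _model_frame(cohort: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    frame = cohort[list(dict.fromkeys(columns))].dropna()
    return frame


def fit_ddi_logistic(cohort: pd.DataFrame, predictor: str,
                     config: AnalysisConfig = AnalysisConfig()) -> list[RegressionResult]:
    """One logistic model: ddi_status ~ predictor + fixed adjustment block.

    Complete-case; reports exp(coef) with Wald 95% CIs for every non-intercept
    term.  Coefficients beyond ``SEPARATION_BOUND`` in absolute value flag the
    term as (quasi-)separated.
    """
    covs = [c for c in config.effective_covariates() if c != predictor]
    frame = _model_frame(cohort, ["ddi_status", predictor, *covs])
    frame = frame.assign(ddi_status=frame["ddi_status"].astype(int))
    n_terms = 1 + len(covs) + 1
    if len(frame) < 10 * n_terms:
        raise ValueError(
            f"{predictor}: only {len(frame)} complete cases for ~{n_terms} terms")
    rhs = " + ".join(_term(t, config.categorical, frame) for t in [predictor, *covs])
    model = smf.logit(f"ddi_status ~ {rhs}", data=frame)
    try:
        fit = model.fit(disp=0, maxiter=200)
    except Exception:
        # Newton blows up under (quasi-)separation; BFGS still yields the
        # diverging coefficients, which are then flagged below.
        fit = model.fit(disp=0, maxiter=500, method="bfgs")
    ci = fit.conf_int()
    out = []
    with np.errstate(over="ignore"):    # diverging CIs under separation
        for term in fit.params.index:
            if term == "Intercept":
                continue
            coef = float(fit.params[term])
            out.append(RegressionResult(
                term=term,
                estimate=float(np.exp(coef)),
                ci_low=float(np.exp(ci.loc[term, 0])),
                ci_high=float(np.exp(ci.loc[term, 1])),
                p_value=float(fit.pvalues[term]),
                n_used=int(fit.nobs),
                flag="separation" if abs(coef) > SEPARATION_BOUND else None))
    return out


def fit_duration_model(cohort: pd.DataFrame,
                       config: AnalysisConfig = AnalysisConfig()) -> list[RegressionResult]:
    """Linear model of longest co-prescription overlap on CYP2C19 phenotype.

    Restricted to DDI participants with a usable overlap duration and a
    determinate phenotype; normal metabolisers are the reference; the
    citalopram-duration covariate is always dropped from the adjustment block
    (it is nearly collinear with the outcome).  Judged at nominal alpha.
    """
    covs = [c for c in config.effective_covariates()
            if c not in ("cital_longest_days",)]
    sub = cohort.loc[cohort["ddi_status"].astype(bool)
                     & ~cohort["durations_excluded"].astype(bool)
                     & cohort["cyp2c19_phenotype"].notna()].copy()
    if sub.empty or (sub["cyp2c19_phenotype"] != "NM").sum() == 0 \
            or (sub["cyp2c19_phenotype"] == "NM").sum() == 0:
        return [RegressionResult("cyp2c19_phenotype", np.nan, np.nan, np.nan,
                                 np.nan, int(len(sub)), flag="untestable")]
    outcome = "longest_overlap_days"
    if config.duration_log1p:
        sub["log1p_overlap"] = np.log1p(sub[outcome].astype(float))
        outcome = "log1p_overlap"
    sub["cyp2c19_phenotype"] = sub["cyp2c19_phenotype"].astype(str)
    frame = _model_frame(sub, [outcome, "cyp2c19_phenotype", *covs])
    rhs = " + ".join(["C(cyp2c19_phenotype, Treatment('NM'))",
                      *(_term(c, config.categorical, frame) for c in covs)])
    fit = smf.ols(f"{outcome} ~ {rhs}", data=frame).fit()
    ci = fit.conf_int()
    out = []
    for term in fit.params.index:
        if "cyp2c19_phenotype" not in term:
            continue
        out.append(RegressionResult(
            term=term, estimate=float(fit.params[term]),
            ci_low=float(ci.loc[term, 0]), ci_high=float(ci.loc[term, 1]),
            p_value=float(fit.pvalues[term]), n_used=int(fit.nobs)))
    return out


# ---------------------------------------------------------------------------
# Analysis bundles and the sensitivity suite
# ---------------------------------------------------------------------------

DEFAULT_VARIABLES: dict[str, str] = {
    "sex": "categorical",
    "age_at_first_citalopram": "continuous",
    "townsend": "continuous",
    "qualifications": "categorical",
    "bmi": "continuous",
    "ethnicity": "categorical",
    "ever_smoked": "categorical",
    "depression": "categorical",
    "anxiety": "categorical",
    "trd": "categorical",
    "suicidality": "categorical",
    "heart_attack": "categorical",
    "diabetes": "categorical",
    "hypertension": "categorical",
    "cancer": "categorical",
    "stroke": "categorical",
    "angina": "categorical",
}

DEFAULT_PREDICTORS = ("trd", "suicidality", "heart_attack", "anxiety",
                      "depression", "diabetes")


@dataclass
class AnalysisResults:
    """Everything one analysis mode produces, shaped identically across modes."""
    mode: str
    alpha_bonf: float
    counts: dict[str, int]
    univariate: list[UnivariateResult]
    logistic: dict[str, list[RegressionResult]]
    duration: list[RegressionResult] | None
    ddi_participants: frozenset = field(default_factory=frozenset)


def run_analysis(cohort: pd.DataFrame,
                 config: AnalysisConfig = AnalysisConfig(),
                 variables: Mapping[str, str] | None = None,
                 predictors: Sequence[str] | None = None,
                 counts: dict[str, int] | None = None) -> AnalysisResults:
    """Univariate screen + per-predictor logistic fits (+ duration model if a
    phenotype column is attached) on an assembled cohort table."""
    if variables is None:
        variables = {k: v for k, v in DEFAULT_VARIABLES.items()
                     if k in cohort.columns}
        if "cyp2c19_phenotype" in cohort.columns:
            variables = {**variables, "cyp2c19_phenotype": "categorical"}
    if predictors is None:
        predictors = [p for p in DEFAULT_PREDICTORS if p in cohort.columns]
    uni = univariate_screen(cohort, variables, config)
    logistic = {p: fit_ddi_logistic(cohort, p, config) for p in predictors}
    duration = (fit_duration_model(cohort, config)
                if "cyp2c19_phenotype" in cohort.columns else None)
    return AnalysisResults(
        mode=config.mode, alpha_bonf=config.alpha_bonf,
        counts=counts or {}, univariate=uni, logistic=logistic,
        duration=duration,
        ddi_participants=frozenset(
            cohort.loc[cohort["ddi_status"].astype(bool), "participant_id"]))


def run_sensitivity(events: pd.DataFrame,
                    covariates: pd.DataFrame,
                    catalog: Catalog,
                    config: AnalysisConfig = AnalysisConfig(),
                    diplotypes: pd.DataFrame | None = None,
                    modes: Sequence[str] = SENSITIVITY_MODES,
                    variables: Mapping[str, str] | None = None,
                    predictors: Sequence[str] | None = None) -> dict[str, AnalysisResults]:
    """Run the main analysis plus the requested sensitivity modes.

    Modes (a)/(b) rebuild the exposure table through the corresponding
    catalogue filter; (c)/(d) reuse the main cohort and only change the
    adjustment block.  Results share one structure so modes can be diffed.
    """
    from .cyp2c19 import attach_phenotypes

    out: dict[str, AnalysisResults] = {}
    cohort_cache: dict[str, tuple[pd.DataFrame, dict[str, int]]] = {}
    for mode in modes:
        filt = _MODE_TO_FILTER[mode]
        if filt not in cohort_cache:
            build = build_cohort(events, covariates, catalog, mode=filt)
            cohort = build.cohort
            if diplotypes is not None:
                cohort = attach_phenotypes(cohort, diplotypes)
            cohort_cache[filt] = (cohort, build.counts)
        cohort, counts = cohort_cache[filt]
        out[mode] = run_analysis(cohort, replace(config, mode=mode),
                                 variables=variables, predictors=predictors,
                                 counts=counts)
    return out
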