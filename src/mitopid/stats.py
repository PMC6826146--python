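"""Cohort-level statistics for burden and heteroplasmy.

Burden frequencies (per 10,000 bp) are heavily right-skewed, so they are
ln(x+1)-transformed before linear modelling.  The core models are:

* ANCOVA of transformed burden on age (years), smoking status
  (current/never), and trichotomized HIV status (negative / positive with
  peak plasma viral load < 100,000 copies/ml / positive with peak pVL >=
  100,000) — the two HIV indicators are coded against the negative reference.
* Binary logistic regression of heteroplasmy (yes/no) on age, smoking,
  trichotomized HIV, and an age x smoking interaction, with within-stratum
  refits by smoking status to display the interaction.

A univariate screening battery (test per variable type) feeds a two-stage
covariate selection: univariate p < .1, then the candidate must lower the
multivariable model's AIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

log = logging.getLogger(__name__)

HIV3_LEVELS = ("negative", "positive_low_peak", "positive_high_peak")
SMOKING_LEVELS = ("never", "current")

BURDEN_FORMULA = (
    "burden_t ~ age + C(smoking, Treatment('never')) "
    "+ C(hiv3, Treatment('negative'))"
)
HETEROPLASMY_FORMULA = (
    "heteroplasmy ~ age + smoker + age:smoker + C(hiv3, Treatment('negative'))"
)


class SeparationError(RuntimeError):
    """Logistic fit aborted: the outcome is (quasi-)completely separated."""


def ln1p_transform(x):
    """Variance-stabilising transform y = ln(x + 1); x must be >= 0."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("burden frequencies must be non-negative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) else out


def ln1p_inverse(y):
    """Inverse transform x = exp(y) - 1."""
    arr = np.asarray(y, dtype=float)
    out = np.expm1(arr)
    return float(out) if np.isscalar(y) else out


@dataclass
class ModelFit:
    """A fitted model's terms, effects, intervals, p-values, and fit quality."""

    terms: list[str]
    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    r2: float
    r2_kind: str  # "ols" | "nagelkerke"
    r2_mcfadden: float | None
    n: int
    formula: str
    aic: float

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "n": self.n,
            "r2": self.r2,
            "r2_kind": self.r2_kind,
            "r2_mcfadden": self.r2_mcfadden,
            "aic": self.aic,
            "terms": {
                t: {
                    "beta": self.params[t],
                    "ci95": list(self.conf_int[t]),
                    "p": self.pvalues[t],
                }
                for t in self.terms
            },
        }


def _wrap_fit(res, formula: str, kind: str) -> ModelFit:
    terms = list(res.params.index)
    ci = res.conf_int()
    if kind == "ols":
        r2, r2_kind, mcf = float(res.rsquared), "ols", None
    else:
        n = int(res.nobs)
        llf, llnull = res.llf, res.llnull
        cox_snell = 1 - math.exp(2 * (llnull - llf) / n)
        denom = 1 - math.exp(2 * llnull / n)
        r2 = cox_snell / denom if denom > 0 else float("nan")
        r2_kind = "nagelkerke"
        mcf = float(1 - llf / llnull) if llnull != 0 else float("nan")
    return ModelFit(
        terms=terms,
        params={t: float(res.params[t]) for t in terms},
        conf_int={t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in terms},
        pvalues={t: float(res.pvalues[t]) for t in terms},
        r2=r2,
        r2_kind=r2_kind,
        r2_mcfadden=mcf,
        n=int(res.nobs),
        formula=formula,
        aic=float(res.aic),
    )


def _prepare(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "burden_t" not in df and "freq_per_10kb" in df:
        df["burden_t"] = ln1p_transform(df["freq_per_10kb"].to_numpy())
    if "smoker" not in df and "smoking" in df:
        df["smoker"] = (df["smoking"] == "current").astype(int)
    if "heteroplasmy" in df:
        df["heteroplasmy"] = df["heteroplasmy"].astype(int)
    return df


def fit_burden_ancova(
    cohort: pd.DataFrame,
    extra_terms: tuple[str, ...] = (),
    formula: str | None = None,
) -> ModelFit:
    """ANCOVA of ln(x+1) burden on age + smoking + trichotomized HIV.

    Complete-case deletion per model; requires n >= 10 observations per model
    term as a stability guard.  Raises on a rank-deficient design, naming the
    aliased terms.
    """
    df = _prepare(cohort)
    f = formula or BURDEN_FORMULA
    for term in extra_terms:
        f += f" + {term}"
    model = smf.ols(f, data=df)
    n_terms = model.exog.shape[1]
    if model.exog.shape[0] < 10 * n_terms:
        raise ValueError(
            f"n = {model.exog.shape[0]} too small for {n_terms} model terms"
        )
    rank = np.linalg.matrix_rank(model.exog)
    if rank < n_terms:
        raise np.linalg.LinAlgError(
            f"design matrix rank-deficient ({rank} < {n_terms}); "
            f"check aliased terms among {model.exog_names}"
        )
    return _wrap_fit(model.fit(), f, "ols")


def _check_separation(res, threshold: float = 1e-6) -> None:
    fitted = res.predict()
    if np.all((fitted < threshold) | (fitted > 1 - threshold)):
        raise SeparationError(
            "complete separation: all fitted probabilities are 0 or 1"
        )


def fit_heteroplasmy_logistic(
    cohort: pd.DataFrame,
    extra_terms: tuple[str, ...] = (),
    formula: str | None = None,
    stratified: bool = True,
) -> tuple[ModelFit, dict[str, ModelFit]]:
    """Binary logistic fit of heteroplasmy with an age x smoking interaction.

    Returns the full-cohort fit and, when ``stratified``, refits of
    ``heteroplasmy ~ age`` within current smokers and never smokers, which
    display the interaction as opposite-signed age slopes.  Pseudo-R² is
    Nagelkerke (McFadden also reported).
    """
    df = _prepare(cohort)
    if df["heteroplasmy"].nunique() < 2:
        raise ValueError("both heteroplasmy outcome classes must be present")
    f = formula or HETEROPLASMY_FORMULA
    for term in extra_terms:
        f += f" + {term}"
    try:
        res = smf.logit(f, data=df).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    _check_separation(res)
    fit = _wrap_fit(res, f, "logit")
    strata: dict[str, ModelFit] = {}
    if stratified:
        for label, mask in (
            ("current", df["smoker"] == 1),
            ("never", df["smoker"] == 0),
        ):
            sub = df[mask]
            if sub["heteroplasmy"].nunique() < 2:
                log.warning("stratum %s has a single outcome class; skipped", label)
                continue
            sub_res = smf.logit("heteroplasmy ~ age", data=sub).fit(disp=0)
            strata[label] = _wrap_fit(sub_res, "heteroplasmy ~ age", "logit")
    return fit, strata


# variable -> (test name, callable) mapping for the univariate screen
def _linreg(df, var, outcome):
    sub = df[[var, outcome]].dropna()
    res = sps.linregress(sub[var], sub[outcome])
    return res.slope, res.pvalue, len(sub)


def _spearman(df, var, outcome):
    sub = df[[var, outcome]].dropna()
    rho, p = sps.spearmanr(sub[var], sub[outcome])
    return rho, p, len(sub)


def _mannwhitney(df, var, outcome):
    sub = df[[var, outcome]].dropna()
    levels = sub[var].unique()
    if len(levels) != 2:
        raise ValueError(f"{var}: Mann-Whitney needs exactly 2 groups")
    a = sub.loc[sub[var] == levels[0], outcome]
    b = sub.loc[sub[var] == levels[1], outcome]
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return stat, p, len(sub)


def _kruskal(df, var, outcome):
    sub = df[[var, outcome]].dropna()
    groups = [g[outcome].to_numpy() for _, g in sub.groupby(var) if len(g) > 0]
    if len(groups) < 2:
        raise ValueError(f"{var}: Kruskal-Wallis needs >= 2 groups")
    if all(np.array_equal(np.sort(g), np.sort(groups[0])) for g in groups):
        return 0.0, 1.0, len(sub)  # identical groups: null centre
    stat, p = sps.kruskal(*groups)
    return stat, p, len(sub)


def _fisher_or_chi2(df, var, outcome):
    sub = df[[var, outcome]].dropna()
    table = pd.crosstab(sub[var], sub[outcome])
    if table.shape == (2, 2):
        _, p = sps.fisher_exact(table.to_numpy())
        return float("nan"), p, len(sub)
    stat, p, _, _ = sps.chi2_contingency(table.to_numpy())
    return stat, p, len(sub)


DEFAULT_UNIVARIATE_TESTS: dict[str, tuple[str, str]] = {
    # variable: (test for the continuous burden outcome, test for binary heteroplasmy)
    "age": ("linear_regression", "logit_screen"),
    "bmi_log": ("linear_regression", "logit_screen"),
    "cd4_current": ("linear_regression", "logit_screen"),
    "cd4_nadir": ("spearman", "logit_screen"),
    "smoking": ("mann_whitney", "fisher"),
    "current_pvl_detectable": ("mann_whitney", "fisher"),
    "peak_pvl_high": ("mann_whitney", "fisher"),
    "hiv3": ("kruskal_wallis", "chi2"),
    "ethnicity": ("kruskal_wallis", "chi2"),
}


def univariate_battery(
    cohort: pd.DataFrame,
    outcome: str = "burden_t",
    tests: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-variable association screen against a continuous or binary outcome.

    The test for each variable follows its type: linear regression for
    continuous covariates (log BMI, current CD4, age), Spearman for CD4
    nadir, Mann-Whitney for two-level factors, Kruskal-Wallis for multi-level
    factors; for the binary heteroplasmy outcome, factors use Fisher/chi²
    and continuous covariates a single-term logistic screen.  All-missing
    variables are skipped with a warning.  Returns one row per variable.
    """
    df = _prepare(cohort)
    tests = tests or DEFAULT_UNIVARIATE_TESTS
    binary_outcome = df[outcome].dropna().nunique() <= 2
    rows = []
    for var, (cont_test, bin_test) in tests.items():
        if var not in df.columns or df[var].dropna().empty:
            log.warning("univariate screen: %s missing or all-NA; skipped", var)
            continue
        test = bin_test if binary_outcome else cont_test
        try:
            if test == "linear_regression":
                stat, p, n = _linreg(df, var, outcome)
            elif test == "spearman":
                stat, p, n = _spearman(df, var, outcome)
            elif test == "mann_whitney":
                stat, p, n = _mannwhitney(df, var, outcome)
            elif test == "kruskal_wallis":
                stat, p, n = _kruskal(df, var, outcome)
            elif test in ("fisher", "chi2"):
                stat, p, n = _fisher_or_chi2(df, var, outcome)
            elif test == "logit_screen":
                sub = df[[var, outcome]].dropna()
                res = smf.logit(f"{outcome} ~ {var}", data=sub).fit(disp=0)
                stat, p, n = float(res.params[var]), float(res.pvalues[var]), len(sub)
            else:
                raise ValueError(f"unknown test {test}")
        except ValueError as exc:
            log.warning("univariate screen: %s skipped (%s)", var, exc)
            continue
        rows.append(
            {"variable": var, "test": test, "statistic": stat, "p": p, "n": n}
        )
    return pd.DataFrame(rows, columns=["variable", "test", "statistic", "p", "n"])


def select_covariates(
    univariate: pd.DataFrame,
    cohort: pd.DataFrame,
    candidates: dict[str, str],
    p_screen: float = 0.1,
    fit_fn=fit_burden_ancova,
) -> tuple[list[str], list[str]]:
    """Two-stage covariate selection for the multivariable models.

    Base terms (age, smoking, hiv3) are always included.  A candidate enters
    iff its univariate p < ``p_screen`` AND adding it lowers the model AIC.
    ``candidates`` maps variable name (as in the univariate table) to the
    formula term to add.  Returns ``(selected terms, log lines)``.
    """
    base_fit = fit_fn(cohort)
    selected: list[str] = []
    log_lines: list[str] = [f"base AIC = {base_fit.aic:.3f}"]
    pvals = dict(zip(univariate["variable"], univariate["p"]))
    current_aic = base_fit.aic
    for var, term in candidates.items():
        p = pvals.get(var)
        if p is None or not (p < p_screen):
            log_lines.append(f"{var}: univariate p={p} >= {p_screen}; not added")
            continue
        trial = fit_fn(cohort, extra_terms=tuple(selected) + (term,))
        if trial.aic < current_aic:
            selected.append(term)
            current_aic = trial.aic
            log_lines.append(f"{var}: p={p:.4g}, AIC -> {trial.aic:.3f}; added")
        else:
            log_lines.append(
                f"{var}: p={p:.4g} passed screen but AIC {trial.aic:.3f} "
                f">= {current_aic:.3f}; not added"
            )
    return selected, log_lines
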