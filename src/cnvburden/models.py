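"""The association battery: logistic, ordered-logit, linear, Cox, Poisson
and multinomial fits with the per-analysis covariate presets, effect
reporting on the published scales, and Bonferroni adjustment.

Every fit reports the exposure term only as the headline estimate (on the
log scale for ratio families), with the full coefficient table retained for
inspection. Confidence intervals are Wald, symmetric on the linear-predictor
scale: ``ci95 = exp(estimate +/- 1.96 se)`` for the ratio families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import ConvergenceWarning, \
    PerfectSeparationError, PerfectSeparationWarning

from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "ModelSpec",
    "AssocResult",
    "COVARIATE_PRESETS",
    "preset_covariates",
    "fit_association",
    "per_sd_effect",
    "bonferroni",
]

FAMILIES = ("logistic", "ordered_logit", "linear", "cox", "poisson",
            "multinomial")

RATIO_FAMILIES = ("logistic", "ordered_logit", "cox", "poisson",
                  "multinomial")

_PCS = [f"pc{i}" for i in range(1, 11)]

# Covariate presets mirroring the study's per-analysis adjustment sets.
COVARIATE_PRESETS: dict[str, list[str]] = {
    "snpd_logistic": ["log_age", "sex", *_PCS, "enrollment_year"],
    "education_ologit": ["age", "sex", *_PCS],
    "education_years_linear": ["age", "sex", "baseline_year", *_PCS],
    "income_ologit": ["age", "sex", *_PCS, "household_size"],
    "income_ologit_adj_education": ["age", "sex", *_PCS, "household_size",
                                    "education_level"],
    "health_ologit": ["age", "sex", *_PCS],
    "cci_poisson": ["age", "sex", *_PCS, "enrollment_year"],
    "mortality_cox": ["age", "sex", *_PCS],
    "mortality_cox_lifestyle": ["age", "sex", *_PCS, "smoking", "bmi",
                                "alcohol"],
    "ses_multinomial": ["sex", "age", "enrollment_year", *_PCS],
}


def preset_covariates(name: str) -> list[str]:
    if name not in COVARIATE_PRESETS:
        raise KeyError(f"unknown covariate preset {name!r}")
    return list(COVARIATE_PRESETS[name])


@dataclass(frozen=True)
class ModelSpec:
    """One regression to run: family, outcome, exposure and covariates.

    ``exposure`` is either a binary carrier/group indicator or a continuous
    standardized score (per-SD effects). For Cox fits ``outcome`` is the
    duration column and ``event_col`` the event indicator; for multinomial
    fits ``reference`` is the outcome category treated as baseline.
    """

    family: str
    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    event_col: str = "death"
    reference: int = 2

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def columns(self) -> list[str]:
        cols = [self.outcome, self.exposure, *self.covariates]
        if self.family == "cox":
            cols.append(self.event_col)
        return cols


@dataclass
class AssocResult:
    """Exposure effect from one fit.

    ``estimate`` is on the log scale for ratio families (log-OR / log-HR /
    log-IRR) and in outcome units for linear fits; ``ci95`` is on the
    reported (ratio or linear) scale.
    """

    estimate: float
    se: float
    p: float
    n_used: int
    family: str
    exposure: str
    outcome: str
    cohort: str = ""
    contrast: str = ""
    p_adj: float | None = None
    converged: bool = True
    note: str = ""
    coef_table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def ratio(self) -> float:
        """exp(estimate): OR / HR / IRR for log-link families."""
        return float(np.exp(self.estimate))

    @property
    def ci95(self) -> tuple[float, float]:
        lo = self.estimate - 1.96 * self.se
        hi = self.estimate + 1.96 * self.se
        if self.family in RATIO_FAMILIES:
            return (float(np.exp(lo)), float(np.exp(hi)))
        return (float(lo), float(hi))

    def __str__(self) -> str:
        lo, hi = self.ci95
        point = self.ratio if self.family in RATIO_FAMILIES else self.estimate
        label = {"logistic": "OR", "ordered_logit": "OR", "cox": "HR",
                 "poisson": "IRR", "multinomial": "OR"}.get(self.family, "beta")
        return (f"{self.outcome} ~ {self.exposure} [{self.family}]: "
                f"{label} = {point:.2f} [{lo:.2f}-{hi:.2f}], p = {self.p:.2g}, "
                f"n = {self.n_used}")


def _check_exposure(x: pd.Series) -> None:
    if x.nunique() < 2:
        raise ValueError(f"exposure {x.name!r} has zero variance")


def _design(df: pd.DataFrame, spec: ModelSpec, const: bool):
    cols = [spec.exposure, *spec.covariates]
    missing = [c for c in cols + [spec.outcome] if c not in df.columns]
    if missing:
        raise ValueError(f"columns missing from table: {missing}")
    sub = df[spec.columns()].dropna()
    X = sub[cols].astype(float)
    if const:
        X = sm.add_constant(X, has_constant="add")
    return sub, X


def fit_association(
    table: pd.DataFrame, spec: ModelSpec, cohort: str = ""
) -> AssocResult | list[AssocResult]:
    """Maximum-likelihood fit of the specified family; returns the exposure
    effect (a list of two contrasts for the multinomial family: group 1 vs
    reference and group 3 vs reference).

    Non-convergence or separation is reported on the result (``converged``
    False with a note), not raised, so batteries over many outcomes do not
    abort; a zero-variance exposure is an error.
    """
    fitter = {
        "logistic": _fit_logistic,
        "ordered_logit": _fit_ologit,
        "linear": _fit_linear,
        "poisson": _fit_poisson,
        "cox": _fit_cox,
        "multinomial": _fit_multinomial,
    }[spec.family]
    res = fitter(table, spec)
    if isinstance(res, list):
        for r in res:
            r.cohort = cohort
    else:
        res.cohort = cohort
    return res


def _wrap(params, bse, pvals, spec, n, coef_table, converged, note="",
          contrast=""):
    return AssocResult(
        estimate=float(params[spec.exposure]),
        se=float(bse[spec.exposure]),
        p=float(pvals[spec.exposure]),
        n_used=n,
        family=spec.family,
        exposure=spec.exposure,
        outcome=spec.outcome,
        contrast=contrast,
        converged=converged,
        note=note,
        coef_table=coef_table,
    )


def _fit_glm_like(table, spec, model_cls, **model_kw):
    sub, X = _design(table, spec, const=True)
    _check_exposure(sub[spec.exposure])
    y = sub[spec.outcome].astype(float)
    converged, note = True, ""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model_cls(y, X, **model_kw).fit(disp=0)
        except (ConvergenceWarning, PerfectSeparationWarning,
                PerfectSeparationError, np.linalg.LinAlgError) as exc:
            converged, note = False, f"{type(exc).__name__}: {exc}"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = model_cls(y, X, **model_kw).fit(disp=0, maxiter=200)
            except Exception:
                nan = pd.Series(np.nan, index=X.columns)
                return _wrap(nan, nan, nan, spec, len(sub),
                             pd.DataFrame({"coef": nan, "se": nan, "p": nan}),
                             False, note)
    tab = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return _wrap(fit.params, fit.bse, fit.pvalues, spec, len(sub), tab,
                 converged, note)


def _fit_logistic(table, spec):
    return _fit_glm_like(table, spec, sm.Logit)


def _fit_linear(table, spec):
    sub, X = _design(table, spec, const=True)
    _check_exposure(sub[spec.exposure])
    fit = sm.OLS(sub[spec.outcome].astype(float), X).fit()
    tab = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return _wrap(fit.params, fit.bse, fit.pvalues, spec, len(sub), tab, True)


def _fit_poisson(table, spec):
    return _fit_glm_like(table, spec, sm.GLM,
                         family=sm.families.Poisson())


class _OrderedLogit(OrderedModel):
    """statsmodels OrderedModel with the analytic proportional-odds score.

    The parent differentiates the log-likelihood numerically, which
    dominates fit time on cohort-sized tables; the gradient of the
    cumulative-logit likelihood is closed-form, so supply it. Parameters,
    likelihood and the threshold reparameterization (first cut point raw,
    remaining increments on the log scale) are the parent's.
    """

    def score(self, params):  # noqa: D102 - contract from parent
        k = self.k_vars
        beta = np.asarray(params[:k], dtype=float)
        th_params = np.asarray(params[k:], dtype=float)
        alpha = self.transform_threshold_params(th_params)
        xb = self.exog @ beta
        y = self.endog
        lo = alpha[y] - xb
        hi = alpha[y + 1] - xb
        prob = np.clip(stats.logistic.cdf(hi) - stats.logistic.cdf(lo),
                       1e-300, None)
        f_hi = stats.logistic.pdf(hi)
        f_lo = stats.logistic.pdf(lo)
        g_beta = self.exog.T @ ((f_lo - f_hi) / prob)
        n_cuts = len(alpha) - 2
        g_alpha = np.zeros(n_cuts)
        w_hi = f_hi / prob
        w_lo = -f_lo / prob
        for j in range(1, n_cuts + 1):
            g_alpha[j - 1] = w_hi[y + 1 == j].sum() + w_lo[y == j].sum()
        g_t = np.zeros(n_cuts)
        g_t[0] = g_alpha.sum()
        if n_cuts > 1:
            expt = np.exp(th_params[1:])
            for m in range(1, n_cuts):
                g_t[m] = expt[m - 1] * g_alpha[m:].sum()
        return np.r_[g_beta, g_t]


def _fit_ologit(table, spec):
    sub, X = _design(table, spec, const=False)
    _check_exposure(sub[spec.exposure])
    y = sub[spec.outcome].astype(float)
    if y.nunique() < 3:
        raise ValueError("ordered_logit requires >= 3 outcome categories")
    model = _OrderedLogit(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # optimizer chatter
        fit = model.fit(method="bfgs", maxiter=200, disp=False)
    converged = bool(fit.mle_retvals.get("converged", True))
    note = "" if converged else "bfgs did not converge"
    tab = pd.DataFrame({"coef": fit.params, "se": fit.bse, "p": fit.pvalues})
    return _wrap(fit.params, fit.bse, fit.pvalues, spec, len(sub), tab,
                 converged, note)


def _fit_cox(table, spec):
    cols = spec.columns()
    sub = table[cols].dropna()
    _check_exposure(sub[spec.exposure])
    cph = CoxPHFitter()
    converged, note = True, ""
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(sub.astype(float), duration_col=spec.outcome,
                    event_col=spec.event_col)
    except ConvergenceError as exc:
        return AssocResult(
            estimate=float("nan"), se=float("nan"), p=float("nan"),
            n_used=len(sub), family=spec.family, exposure=spec.exposure,
            outcome=spec.outcome, converged=False, note=str(exc),
        )
    s = cph.summary
    tab = pd.DataFrame({"coef": s["coef"], "se": s["se(coef)"], "p": s["p"]})
    return _wrap(s["coef"], s["se(coef)"], s["p"], spec, len(sub), tab,
                 converged, note)


def _fit_multinomial(table, spec):
    """Multinomial logit of the SES grouping with the reference category as
    baseline; returns one contrast per non-reference group (1 vs ref,
    3 vs ref)."""
    sub, X = _design(table, spec, const=True)
    _check_exposure(sub[spec.exposure])
    y_raw = sub[spec.outcome].astype(int)
    groups = sorted(y_raw.unique())
    if spec.reference not in groups:
        raise ValueError(f"reference group {spec.reference} absent from outcome")
    # MNLogit baselines on the lowest code: remap reference -> 0.
    others = [g for g in groups if g != spec.reference]
    code = {spec.reference: 0, **{g: i + 1 for i, g in enumerate(others)}}
    y = y_raw.map(code)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    results = []
    for i, g in enumerate(others):
        params = fit.params[i]
        bse = fit.bse[i]
        pvals = fit.pvalues[i]
        tab = pd.DataFrame({"coef": params, "se": bse, "p": pvals})
        results.append(
            _wrap(params, bse, pvals, spec, len(sub), tab,
                  bool(fit.mle_retvals.get("converged", True)),
                  contrast=f"{g}_vs_{spec.reference}")
        )
    return results


def per_sd_effect(
    table: pd.DataFrame, spec: ModelSpec, cohort: str = ""
) -> AssocResult | list[AssocResult]:
    """Fit with the exposure standardized within the table (z-score), so the
    reported estimate is per +1 SD of the raw score."""
    x = table[spec.exposure]
    sd = x.std(ddof=1)
    if not sd > 0:
        raise ValueError(f"exposure {spec.exposure!r} has zero variance")
    zcol = f"{spec.exposure}_z"
    table = table.assign(**{zcol: (x - x.mean()) / sd})
    return fit_association(table, replace(spec, exposure=zcol), cohort)


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: ``p_adj = min(1, m * p)``.

    ``m`` is the explicit family size and must cover the tests submitted.
    """
    p = np.asarray(p_values, dtype=float)
    if m < p.size:
        raise ValueError(f"family size m={m} smaller than {p.size} tests")
    adj = np.minimum(1.0, m * p)
    if np.isscalar(p_values) or np.ndim(p_values) == 0:
        return float(adj)
    return adj
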