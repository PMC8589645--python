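"""Derived analysis phenotypes: SNPD status, the three-level SES/health
grouping, the Charlson comorbidity index, and per-analysis eligibility
filters.

SNPD (severe neurological and psychiatric disorder) covers intellectual
disability, schizophrenia, epilepsy, bipolar disorder, major depressive
disorder, childhood behavioural disorders and disorders of psychiatric
development; the joint "any SNPD" flag deliberately excludes depression.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SNPD_PHENOTYPES",
    "CHARLSON_WEIGHTS_DEFAULT",
    "derive_snpd",
    "ses_group",
    "ses_groups",
    "charlson_index",
    "eligibility_filter",
]

SNPD_PHENOTYPES = ("ID", "SCZ", "EPI", "BD", "MDD", "CBD", "PDD")

# Classic Charlson weight map (synthetic stand-in for the study's own
# 20-phenotype registry mapping, which is not published in the main text);
# user-overridable wherever a weight map is accepted.
CHARLSON_WEIGHTS_DEFAULT: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "peripheral_vascular_disease": 1,
    "cerebrovascular_disease": 1,
    "dementia": 1,
    "chronic_pulmonary_disease": 1,
    "rheumatic_disease": 1,
    "peptic_ulcer_disease": 1,
    "mild_liver_disease": 1,
    "diabetes_uncomplicated": 1,
    "diabetes_complicated": 2,
    "hemiplegia_paraplegia": 2,
    "renal_disease": 2,
    "malignancy": 2,
    "moderate_severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids_hiv": 6,
}


def derive_snpd(
    diagnoses: Mapping[str, Iterable[str]],
    code_map: Mapping[str, str],
) -> pd.DataFrame:
    """Per-sample SNPD phenotype flags from diagnosis code sets.

    ``code_map`` maps condition codes to SNPD phenotype labels (one of
    ``SNPD_PHENOTYPES``); unmapped codes are ignored. ``any_snpd`` is the
    OR over all phenotypes except MDD.
    """
    bad = set(code_map.values()) - set(SNPD_PHENOTYPES)
    if bad:
        raise ValueError(f"code_map targets unknown phenotypes: {sorted(bad)}")
    rows = {}
    for sid, codes in diagnoses.items():
        flags = {p: False for p in SNPD_PHENOTYPES}
        for code in codes:
            pheno = code_map.get(code)
            if pheno is not None:
                flags[pheno] = True
        flags["any_snpd"] = any(flags[p] for p in SNPD_PHENOTYPES if p != "MDD")
        rows[sid] = flags
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=[*SNPD_PHENOTYPES, "any_snpd"])
    out.index.name = "sample_id"
    return out.fillna(False).astype(bool)


def ses_group(
    health: int,
    education_level: int,
    income: int,
    lower_secondary: int = 2,
    upper_secondary: int = 3,
) -> int:
    """Three-level joint SES/health grouping.

    Group 1 ("low SES and poor health"): subjective health average (3) or
    worse AND education at lower-secondary level or lower AND household
    income 5/9 or lower. Group 3 ("high SES and good health"): health
    average or better AND education upper-secondary or higher AND income
    5/9 or better. Everyone else is group 2. Income level 5 belongs to both
    clauses as stated; the education clauses alone force disjointness.

    ``health`` is coded 1 (good) .. 5 (poor). The education marks are ranks
    on the cohort's declared ordinal scale.
    """
    low = health >= 3 and education_level <= lower_secondary and income <= 5
    high = health <= 3 and education_level >= upper_secondary and income >= 5
    if low:
        return 1
    if high:
        return 3
    return 2


def ses_groups(
    df: pd.DataFrame,
    health_col: str = "subjective_health",
    education_col: str = "education_level",
    income_col: str = "household_income",
    lower_secondary: int = 2,
    upper_secondary: int = 3,
) -> pd.Series:
    """Vectorized :func:`ses_group` over complete records (callers apply
    the eligibility filter first)."""
    h = df[health_col]
    e = df[education_col]
    i = df[income_col]
    if h.isna().any() or e.isna().any() or i.isna().any():
        raise ValueError("ses_groups requires complete records; "
                         "apply eligibility_filter('ses_grouping') first")
    low = (h >= 3) & (e <= lower_secondary) & (i <= 5)
    high = (h <= 3) & (e >= upper_secondary) & (i >= 5)
    out = pd.Series(2, index=df.index, name="ses_group")
    out[low] = 1
    out[high] = 3
    return out


def charlson_index(
    diagnoses: Iterable[str],
    weight_map: Mapping[str, int] | None = None,
) -> int:
    """Weighted comorbidity index: sum of weights over the distinct
    conditions present in the weight map."""
    weights = CHARLSON_WEIGHTS_DEFAULT if weight_map is None else weight_map
    for cond, w in weights.items():
        if w <= 0:
            raise ValueError(f"weight for {cond!r} must be positive")
    return sum(weights[c] for c in set(diagnoses) if c in weights)


ANALYSES = ("education", "education_years", "income", "health",
            "ses_grouping", "mortality", "cci")


def eligibility_filter(
    records: pd.DataFrame, analysis: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the per-analysis exclusions; returns (kept, report).

    The report has one row per exclusion reason with its count; reasons are
    applied sequentially so counts sum with the kept rows to the input.

    Exclusions by analysis:
      education: education reported unfinished ("ongoing"), "other", or
        missing; education_years additionally requires education_years.
      income / health: missing outcome.
      ses_grouping: students, age > 65, and any missing component
        (health, education level, income).
      mortality / cci: missing follow-up information only.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}; one of {ANALYSES}")
    df = records
    steps: list[tuple[str, pd.Series]] = []  # (reason, drop mask on current df)

    def drop(reason: str, mask: pd.Series) -> None:
        nonlocal df
        steps.append((reason, mask))
        df = df[~mask]

    if analysis in ("education", "education_years"):
        if "education_status" in df.columns:
            drop("education_ongoing", df["education_status"].eq("ongoing"))
            drop("education_other", df["education_status"].eq("other"))
        drop("education_missing", df["education_level"].isna())
        if analysis == "education_years":
            drop("education_years_missing", df["education_years"].isna())
    elif analysis == "income":
        drop("income_missing", df["household_income"].isna())
    elif analysis == "health":
        drop("health_missing", df["subjective_health"].isna())
    elif analysis == "ses_grouping":
        if "student" in df.columns:
            drop("student", df["student"].fillna(False).astype(bool))
        drop("age_over_65", df["age"] > 65)
        drop("health_missing", df["subjective_health"].isna())
        drop("education_missing", df["education_level"].isna())
        drop("income_missing", df["household_income"].isna())
    else:  # mortality, cci
        if "follow_time" in df.columns:
            drop("follow_up_missing", df["follow_time"].isna())

    report = pd.DataFrame(
        [{"reason": r, "n_excluded": int(m.sum())} for r, m in steps],
        columns=["reason", "n_excluded"],
    )
    return df, report
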