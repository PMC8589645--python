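"""End-to-end orchestration: QC -> classification -> PRS grouping ->
phenotype derivation -> association battery -> two-cohort meta-analysis,
with per-stage accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import build_carrier_matrix, carrier_summary, classify_calls, \
    CLASS_COLUMNS
from .meta import MetaInput, meta_auto
from .models import ModelSpec, fit_association, bonferroni, preset_covariates
from .phenotypes import eligibility_filter
from .prs import prs_grouping
from .qc import QcConfig, QcReport, run_qc
from .simulate import SyntheticBundle

__all__ = ["RunConfig", "RunReport", "run_pipeline", "accounting_table"]

# analysis -> (family, outcome column, covariate preset, eligibility key)
ANALYSIS_SPECS: dict[str, tuple[str, str, str, str]] = {
    "education": ("ordered_logit", "education_level", "education_ologit",
                  "education"),
    "income": ("ordered_logit", "household_income", "income_ologit",
               "income"),
    "health": ("ordered_logit", "subjective_health", "health_ologit",
               "health"),
    "snpd": ("logistic", "any_snpd", "snpd_logistic", "mortality"),
    "mortality": ("cox", "follow_time", "mortality_cox", "mortality"),
    "cci": ("poisson", "cci", "cci_poisson", "cci"),
}

PRS_SCORES = (("prs_ea", "low"), ("prs_iq", "low"), ("prs_sz", "high"))


@dataclass(frozen=True)
class RunConfig:
    """What to run and with which thresholds."""

    analyses: tuple[str, ...] = ("education", "income", "health")
    exposures: tuple[str, ...] = ("high_risk", "prs_ea_extreme")
    qc: QcConfig = field(default_factory=QcConfig)
    bonferroni_m: int = 40
    i2_threshold: float = 50.0
    n_prs_cases: int | str = "auto"   # "auto": match high-risk carrier count

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(ANALYSIS_SPECS)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")


@dataclass
class RunReport:
    accounting: pd.DataFrame
    assoc: pd.DataFrame
    meta: pd.DataFrame
    carrier_summaries: dict[str, pd.DataFrame]
    qc_reports: dict[str, QcReport]


def _derive_exposures(bundle: SyntheticBundle, cfg: RunConfig) -> tuple[pd.DataFrame, QcReport, pd.DataFrame]:
    """QC + classify the bundle's calls and attach carrier and PRS-group
    columns to the phenotype table. Falls back to the truth labels when the
    bundle carries no call data."""
    ph = bundle.phenotypes
    if bundle.calls is not None:
        kept, qc_report = run_qc(
            bundle.calls, cfg.qc,
            hla_ig=bundle.regions.get("hla_ig"),
            telo_cent=bundle.regions.get("telo_cent"),
        )
        flags = classify_calls(
            kept, decipher=bundle.regions.get("decipher"),
            genes=bundle.genes,
            assoc_loci={k: bundle.regions[k]
                        for k in ("ea", "income", "medical")
                        if k in bundle.regions},
        )
        carriers = build_carrier_matrix(ph.index, flags)
    else:
        qc_report = QcReport()
        carriers = bundle.truth[CLASS_COLUMNS].copy()

    n_cases = cfg.n_prs_cases
    if n_cases == "auto":
        n_cases = max(1, int(carriers["high_risk"].sum()))
    groups = pd.DataFrame(index=ph.index)
    for score, tail in PRS_SCORES:
        g = prs_grouping(ph[score], n_cases, tail)
        groups[f"{score}_extreme"] = g["label"].eq("extreme_case")
        groups[f"{score}_middle"] = g["label"].eq("middle_control")
    return ph.join(carriers).join(groups), qc_report, carriers


def _eligible_frame(df: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Apply the study design: drop SNPD-diagnosed individuals for the
    socioeconomic/health/mortality analyses, then the per-analysis
    eligibility filter."""
    if analysis != "snpd":
        df = df[~df["any_snpd"]]
    _, _, _, elig = ANALYSIS_SPECS[analysis]
    df, _ = eligibility_filter(df, elig)
    return df


def _comparison_group(df: pd.DataFrame, exposure: str) -> pd.DataFrame:
    """Pick the exposure's comparison set: PRS extremes are compared to the
    middle-quantile controls, CNV classes to non-carriers."""
    if exposure.endswith("_extreme"):
        middle = exposure.replace("_extreme", "_middle")
        return df[df[exposure] | df[middle]]
    return df


def run_pipeline(
    bundles: Mapping[str, SyntheticBundle], cfg: RunConfig | None = None
) -> RunReport:
    """Run the configured analyses on each cohort and meta-analyze across
    cohorts with heterogeneity gating. Deterministic given the bundles."""
    cfg = cfg or RunConfig()
    assoc_rows = []
    accounting_rows = []
    carrier_summaries: dict[str, pd.DataFrame] = {}
    qc_reports: dict[str, QcReport] = {}

    for cohort, bundle in bundles.items():
        df, qc_report, carriers = _derive_exposures(bundle, cfg)
        qc_reports[cohort] = qc_report
        carrier_summaries[cohort] = carrier_summary(carriers)
        acct = {
            "cohort": cohort,
            "phenotyped": len(df),
            "no_snpd": int((~df["any_snpd"]).sum()),
        }
        for analysis in cfg.analyses:
            family, outcome, preset, _ = ANALYSIS_SPECS[analysis]
            eligible = _eligible_frame(df, analysis)
            acct[f"eligible_{analysis}"] = len(eligible)
            for exposure in cfg.exposures:
                sub = _comparison_group(eligible, exposure)
                if sub[exposure].sum() == 0 or (~sub[exposure]).sum() == 0:
                    raise RuntimeError(
                        f"stage assoc/{analysis}: exposure {exposure!r} has "
                        f"no cases or no controls in cohort {cohort}")
                spec = ModelSpec(
                    family=family, outcome=outcome, exposure=exposure,
                    covariates=tuple(preset_covariates(preset)),
                )
                res = fit_association(sub, spec, cohort=cohort)
                results = res if isinstance(res, list) else [res]
                for r in results:
                    assoc_rows.append({
                        "cohort": cohort, "analysis": analysis,
                        "exposure": exposure, "family": family,
                        "estimate": r.estimate, "se": r.se, "p": r.p,
                        "ratio": r.ratio, "ci_lo": r.ci95[0],
                        "ci_hi": r.ci95[1], "n": r.n_used,
                        "converged": r.converged,
                    })
        accounting_rows.append(acct)

    assoc = pd.DataFrame(assoc_rows)
    assoc["p_adj"] = bonferroni(assoc["p"].to_numpy(),
                                max(cfg.bonferroni_m, len(assoc)))

    meta_rows = []
    if len(bundles) >= 2:
        for (analysis, exposure), grp in assoc.groupby(["analysis", "exposure"]):
            if len(grp) < 2:
                continue
            inputs = [MetaInput(r.estimate, r.se, r.cohort)
                      for r in grp.itertuples()]
            m = meta_auto(inputs, i2_threshold=cfg.i2_threshold)
            meta_rows.append({
                "analysis": analysis, "exposure": exposure,
                "estimate": m.estimate, "se": m.se, "p": m.p,
                "ratio": m.ratio, "ci_lo": m.ci95_ratio[0],
                "ci_hi": m.ci95_ratio[1], "Q": m.Q, "I2": m.I2,
                "tau2": m.tau2, "model_used": m.model_used,
                "marker": m.marker,
            })
    meta = pd.DataFrame(meta_rows)

    return RunReport(
        accounting=pd.DataFrame(accounting_rows).set_index("cohort"),
        assoc=assoc, meta=meta,
        carrier_summaries=carrier_summaries, qc_reports=qc_reports,
    )


def accounting_table(report: RunReport) -> pd.DataFrame:
    """Cohort-by-stage participant counts, with a combined row summing the
    cohorts (the counts feeding any cross-cohort meta-analysis)."""
    tab = report.accounting.copy()
    tab.loc["combined"] = tab.sum()
    return tab
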