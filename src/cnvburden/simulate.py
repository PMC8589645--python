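"""Synthetic two-cohort data generator with planted, configurable effects.

The generator emulates the statistical structure the analysis assumes for a
population cohort genotyped on SNP arrays: a CNV landscape in which a small
fraction of samples carry calls constructed to satisfy exactly one
classification rule each (spanning a syndrome region at >= 50%, deleting
>= 50% of the exons of an ID / high-pLI gene, exceeding 1 Mb, or sitting
inside a phenotype-associated locus) while background calls miss every
rule; standard-normal polygenic scores; and ordinal, binary, count and
survival outcomes driven by the same model families the battery fits
(latent-logistic proportional odds, logistic, Poisson, exponential hazards
with administrative censoring).

Everything lives on a small synthetic genome (four chromosomes of a few
Mb) so interval operations run in milliseconds; no real coordinates are
shipped. Applying QC + classification to a generated bundle reproduces the
truth labels exactly, which is what makes planted-effect recovery a
well-defined target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .intervals import CnvCall, GeneModel, GenomicInterval, RegionSet
from .io import write_cnv_calls, write_gene_models, write_region_bed
from .prs import assign_extremes, middle_controls

__all__ = [
    "ScenarioConfig",
    "SyntheticBundle",
    "fixture_regions",
    "fixture_genes",
    "simulate_cnv_landscape",
    "simulate_cohort",
    "write_bundle",
    "SCENARIOS",
    "scenario",
]

CNV_CLASSES = ("decipher", "id_gene_del", "high_pli_del", "large_del",
               "large_dup", "ea_assoc", "income_assoc", "medical_assoc")

HIGH_RISK = CNV_CLASSES[:5]

# Per-class carrier frequencies: defaults for a large population-survey
# cohort, plus an alternative set for a younger birth-style cohort with
# higher frequencies.
DEFAULT_CLASS_FREQS: dict[str, float] = {
    "decipher": 0.0028,
    "id_gene_del": 0.0019,
    "high_pli_del": 0.0115,
    "large_del": 0.0056,
    "large_dup": 0.0088,
    "ea_assoc": 0.0050,
    "income_assoc": 0.0050,
    "medical_assoc": 0.0050,
}
DEFAULT_ANY_HIGH_RISK_FREQ = 0.0249

BIRTH_COHORT_CLASS_FREQS: dict[str, float] = {
    "decipher": 0.0076,
    "id_gene_del": 0.0035,
    "high_pli_del": 0.0159,
    "large_del": 0.0078,
    "large_dup": 0.0108,
    "ea_assoc": 0.0050,
    "income_assoc": 0.0050,
    "medical_assoc": 0.0050,
}
BIRTH_COHORT_ANY_HIGH_RISK_FREQ = 0.0349

# Headline planted effects for the calibrated preset, log scale.
PAPER_CALIBRATED_EFFECTS: dict[tuple[str, str], float] = {
    ("high_risk", "education"): math.log(0.77),
    ("prs_ea_extreme", "education"): math.log(0.31),
    ("high_risk", "income"): math.log(0.77),
    ("income_assoc", "income"): math.log(0.50),
    ("prs_ea_extreme", "income"): math.log(0.66),
    ("medical_assoc", "health"): math.log(0.48),
    ("prs_ea_extreme", "health"): math.log(0.72),
    ("prs_ea_extreme", "mortality"): math.log(1.55),
    ("prs_ea_per_sd", "education_years"): 0.84,
}


# ---------------------------------------------------------------------------
# fixture genome

CHROM_SIZES = {"chr1": 10_000_000, "chr2": 10_000_000,
               "chr3": 10_000_000, "chr4": 6_000_000}


def fixture_regions() -> dict[str, RegionSet]:
    """Synthetic region fixtures: syndrome regions, phenotype-associated
    loci, and artefact (HLA/immunoglobulin, telomere/centromere) regions."""
    iv = GenomicInterval
    return {
        "decipher": RegionSet("decipher", [
            (iv("chr1", 2_000_000, 3_000_000), {"name": "SYN_DEL", "dosage": "del"}),
            (iv("chr1", 4_000_000, 5_000_000), {"name": "SYN_DUP", "dosage": "dup"}),
        ]),
        "ea": RegionSet("ea_assoc_loci", [
            (iv("chr3", 1_000_000, 1_300_000), {"name": "EA_LOC1", "dosage": "del"}),
        ]),
        "income": RegionSet("income_assoc_loci", [
            (iv("chr3", 3_000_000, 3_300_000), {"name": "INC_LOC1", "dosage": "del"}),
        ]),
        "medical": RegionSet("medical_assoc_loci", [
            (iv("chr3", 5_000_000, 5_300_000), {"name": "MED_LOC1", "dosage": "dup"}),
        ]),
        "hla_ig": RegionSet("hla_ig", [
            (iv("chr4", 1_000_000, 1_500_000), {"name": "HLA1"}),
        ]),
        "telo_cent": RegionSet("telo_cent", [
            (iv("chr4", 0, 10_000), {"name": "TEL_4p"}),
            (iv("chr4", 5_990_000, 6_000_000), {"name": "TEL_4q"}),
            (iv("chr4", 2_975_000, 3_025_000), {"name": "CEN_4"}),
        ]),
    }


def fixture_genes() -> list[GeneModel]:
    """Synthetic gene fixtures: one ID-causal gene, one pLI >= 0.95 gene,
    one neutral gene, each with four 10 kb exons."""
    def gene(gene_id, chrom, start, pli, is_id):
        exons = tuple(
            GenomicInterval(chrom, start + off, start + off + 10_000)
            for off in (0, 100_000, 200_000, 390_000)
        )
        return GeneModel(gene_id, GenomicInterval(chrom, start, start + 400_000),
                         exons, pli=pli, is_id_gene=is_id)

    return [
        gene("IDG1", "chr2", 1_000_000, 0.30, True),
        gene("PLIG1", "chr2", 3_000_000, 0.99, False),
        gene("NEUT1", "chr2", 5_000_000, 0.10, False),
    ]


# One call template per class, constructed to satisfy exactly its rule.
_CALL_TEMPLATES: dict[str, tuple[str, int, int, int]] = {
    # class -> (chrom, start, end, cn_state)
    "decipher": ("chr1", 2_200_000, 2_600_000, 1),
    "id_gene_del": ("chr2", 1_090_000, 1_215_000, 1),   # exons 2+3 of IDG1
    "high_pli_del": ("chr2", 3_090_000, 3_215_000, 1),  # exons 2+3 of PLIG1
    "large_del": ("chr3", 6_500_000, 7_700_000, 1),     # 1.2 Mb
    "large_dup": ("chr3", 8_000_000, 9_500_000, 3),     # 1.5 Mb
    "ea_assoc": ("chr3", 1_050_000, 1_250_000, 1),
    "income_assoc": ("chr3", 3_050_000, 3_250_000, 1),
    "medical_assoc": ("chr3", 5_050_000, 5_250_000, 3),
}

# Rule-missing background zone starts on chr1 (spaced so no two background
# calls can ever satisfy the 20% gap merge rule).
_BG_ZONES = (6_000_000, 7_300_000, 8_600_000)
_BG_START_JITTER = 300_000
_BG_MIN_SIZE = 100_000
_BG_MAX_SIZE = 350_000


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic cohort.

    ``class_freqs`` are per-class carrier probabilities. When
    ``any_high_risk_freq`` is set, high-risk carriage is drawn carrier-first:
    a sample is a high-risk carrier with that probability and its carrier
    classes are then sampled in proportion to the per-class frequencies,
    with a second class added at the rate implied by
    ``sum(class freqs) / any_high_risk_freq`` — one CNV carrier can belong
    to several categories, so per-class frequencies sum above the combined
    frequency. When None, classes are independent Bernoulli draws (the mode
    single-class recovery scenarios use). Phenotype-associated (ea/income/
    medical) classes are always independent draws.

    ``planted`` maps (exposure, outcome) to an effect on the log scale for
    ratio families (log-OR / log-HR / log-IRR) and in outcome units for
    ``education_years``. ``n_prs_cases`` sizes the PRS-extreme groups; None
    frequency-matches to the cohort's high-risk carrier count.
    """

    name: str = "custom"
    n_samples: int = 20_000
    cohort: str = "cohortA"
    class_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQS))
    any_high_risk_freq: float | None = DEFAULT_ANY_HIGH_RISK_FREQ
    background_rate: float = 0.65
    planted: Mapping[tuple[str, str], float] = field(default_factory=dict)
    education_probs: tuple[float, ...] = (0.25, 0.35, 0.25, 0.15)
    income_probs: tuple[float, ...] = (0.04, 0.07, 0.11, 0.15, 0.18,
                                       0.17, 0.13, 0.09, 0.06)
    health_probs: tuple[float, ...] = (0.05, 0.10, 0.30, 0.35, 0.20)
    snpd_prevalence: float = 0.037
    mdd_prevalence: float = 0.060
    cci_mean: float = 0.25
    death_base_rate: float = 0.004   # events / person-year
    followup_years: tuple[float, float] = (15.0, 25.0)
    prs_quantile_band: tuple[float, float] = (0.2, 0.8)
    n_prs_cases: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        for cls, f in self.class_freqs.items():
            if cls not in CNV_CLASSES:
                raise ValueError(f"unknown CNV class {cls!r}")
            if not (0 <= f < 1):
                raise ValueError(f"infeasible frequency {f} for {cls}")
        if self.any_high_risk_freq is not None:
            ahr = self.any_high_risk_freq
            if not (0 < ahr < 1):
                raise ValueError(f"infeasible any_high_risk_freq {ahr}")
            hr_sum = sum(self.class_freqs.get(c, 0.0) for c in HIGH_RISK)
            if hr_sum > 0 and not (1.0 <= hr_sum / ahr <= 2.0):
                raise ValueError(
                    "class frequencies imply a mean of "
                    f"{hr_sum / ahr:.3f} classes per carrier; must be in "
                    "[1, 2] (set any_high_risk_freq=None for independent "
                    "class draws)")
        for probs in (self.education_probs, self.income_probs,
                      self.health_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("ordinal base probabilities must sum to 1")


@dataclass
class SyntheticBundle:
    """One simulated cohort: phenotype/PRS table, CNV calls, fixtures, and
    the truth table of planted class labels and PRS group labels."""

    cohort: str
    config: ScenarioConfig
    phenotypes: pd.DataFrame               # covariates, PRS, outcomes
    truth: pd.DataFrame                    # class flags + PRS group labels
    calls: list[CnvCall] | None
    regions: dict[str, RegionSet]
    genes: list[GeneModel]

    @property
    def sample_ids(self) -> pd.Index:
        return self.phenotypes.index

    def analysis_frame(self) -> pd.DataFrame:
        """Phenotypes joined with the truth exposure labels (generator-side
        view; the pipeline derives its own labels from the calls)."""
        return self.phenotypes.join(self.truth)


def simulate_cnv_landscape(
    flags: pd.DataFrame, background_rate: float, rng: np.random.Generator
) -> list[CnvCall]:
    """Build per-sample call lists: one rule-hitting template call per true
    class flag plus Poisson-distributed rule-missing background calls.

    Background sizes are 100 kb plus an exponential tail capped at 350 kb,
    so most calls are no larger than 250 kb; they sit in dedicated zones
    chosen so they can never merge with each other or with template calls.

    A small fraction of samples additionally receive a QC-failing call —
    undersized, under-probed, inside the HLA fixture region, or near a
    telomere — so the QC stages have realistic work to do; none of these
    can reach classification.
    """
    calls: list[CnvCall] = []
    n_bg = np.minimum(rng.poisson(background_rate, size=len(flags)),
                      len(_BG_ZONES))
    starts_jit = rng.integers(0, _BG_START_JITTER, size=(len(flags), 3))
    sizes_raw = _BG_MIN_SIZE + rng.exponential(60_000, size=(len(flags), 3))
    cn_bg = rng.choice([1, 3], size=(len(flags), 3))
    junk_kind = np.where(rng.random(len(flags)) < 0.12,
                         rng.integers(1, 5, size=len(flags)), 0)
    for i, (sid, row) in enumerate(flags.iterrows()):
        for cls in CNV_CLASSES:
            if row[cls]:
                chrom, start, end, cn = _CALL_TEMPLATES[cls]
                calls.append(CnvCall(sid, GenomicInterval(chrom, start, end),
                                     cn, n_probes=(end - start) // 10_000,
                                     source="sim"))
        for j in range(int(n_bg[i])):
            start = _BG_ZONES[j] + int(starts_jit[i, j])
            size = int(min(sizes_raw[i, j], _BG_MAX_SIZE))
            calls.append(CnvCall(sid, GenomicInterval("chr1", start, start + size),
                                 int(cn_bg[i, j]), n_probes=size // 10_000,
                                 source="sim_bg"))
        if junk_kind[i] == 1:    # undersized (chr2, gene-free territory)
            start = 7_000_000 + int(starts_jit[i, 0])
            size = 30_000 + int(starts_jit[i, 1]) // 5
            calls.append(CnvCall(sid, GenomicInterval("chr2", start, start + size),
                                 int(cn_bg[i, 0]), n_probes=max(3, size // 10_000),
                                 source="sim_junk"))
        elif junk_kind[i] == 2:  # enough length, too few probes
            start = 8_500_000 + int(starts_jit[i, 0])
            calls.append(CnvCall(sid, GenomicInterval("chr2", start, start + 120_000),
                                 int(cn_bg[i, 0]), n_probes=5,
                                 source="sim_junk"))
        elif junk_kind[i] == 3:  # inside the HLA/immunoglobulin fixture
            calls.append(CnvCall(sid, GenomicInterval("chr4", 1_050_000, 1_350_000),
                                 int(cn_bg[i, 0]), n_probes=30,
                                 source="sim_junk"))
        elif junk_kind[i] == 4:  # near a telomere
            calls.append(CnvCall(sid, GenomicInterval("chr4", 100_000, 250_000),
                                 int(cn_bg[i, 0]), n_probes=15,
                                 source="sim_junk"))
    return calls


def _ordinal_thresholds(probs: tuple[float, ...]) -> np.ndarray:
    cum = np.cumsum(probs)[:-1]
    return np.log(cum / (1 - cum))  # logistic quantiles


def _draw_ordinal(shift: np.ndarray, probs: tuple[float, ...],
                  rng: np.random.Generator) -> np.ndarray:
    latent = shift + rng.logistic(size=shift.shape[0])
    return np.searchsorted(_ordinal_thresholds(probs), latent) + 1


def _planted_shift(cfg: ScenarioConfig, outcome: str,
                   exposures: pd.DataFrame) -> np.ndarray:
    shift = np.zeros(len(exposures))
    for (exp_name, out_name), beta in cfg.planted.items():
        if out_name != outcome:
            continue
        if exp_name not in exposures.columns:
            raise ValueError(f"planted exposure {exp_name!r} not generated")
        shift = shift + beta * exposures[exp_name].to_numpy(dtype=float)
    return shift


def simulate_cohort(
    cfg: ScenarioConfig, seed: int, with_calls: bool = True
) -> SyntheticBundle:
    """Generate one cohort under the scenario's conditions.

    Reproducible: the same (cfg, seed) yields an identical bundle. With
    ``with_calls=False`` the CNV call list is skipped (the truth labels are
    still present), which is what the replicated recovery experiments use.
    """
    rng = np.random.default_rng(seed)
    n = cfg.n_samples
    sids = pd.Index([f"{cfg.cohort}_{i:06d}" for i in range(n)],
                    name="sample_id")

    # --- carrier truth ------------------------------------------------
    truth = pd.DataFrame(index=sids)
    hr_freqs = np.array([cfg.class_freqs.get(c, 0.0) for c in HIGH_RISK])
    if cfg.any_high_risk_freq is not None and hr_freqs.sum() > 0:
        # carrier-first: union frequency fixed, classes sampled within
        # carriers (one high-risk CNV can belong to several categories)
        flags = np.zeros((n, len(HIGH_RISK)), dtype=bool)
        carrier_idx = np.where(rng.random(n) < cfg.any_high_risk_freq)[0]
        p = hr_freqs / hr_freqs.sum()
        p_second = hr_freqs.sum() / cfg.any_high_risk_freq - 1.0
        second = rng.random(len(carrier_idx)) < p_second
        n_avail = int((hr_freqs > 0).sum())
        for j, i in enumerate(carrier_idx):
            k = 2 if (second[j] and n_avail >= 2) else 1
            chosen = rng.choice(len(HIGH_RISK), size=k, replace=False, p=p)
            flags[i, chosen] = True
        for ci, cls in enumerate(HIGH_RISK):
            truth[cls] = flags[:, ci]
    else:
        for cls in HIGH_RISK:
            truth[cls] = rng.random(n) < cfg.class_freqs.get(cls, 0.0)
    for cls in CNV_CLASSES[5:]:
        truth[cls] = rng.random(n) < cfg.class_freqs.get(cls, 0.0)
    truth["high_risk"] = truth[list(HIGH_RISK)].any(axis=1)

    # --- covariates ---------------------------------------------------
    ph = pd.DataFrame(index=sids)
    ph["age"] = rng.uniform(25, 64, n).round(1)
    ph["log_age"] = np.log(ph["age"])
    ph["sex"] = rng.integers(0, 2, n)
    for i in range(1, 11):
        ph[f"pc{i}"] = rng.standard_normal(n)
    ph["enrollment_year"] = rng.choice([1992, 1997, 2002, 2007], n)
    ph["baseline_year"] = ph["enrollment_year"]
    ph["household_size"] = 1 + rng.poisson(1.3, n)
    ph["student"] = rng.random(n) < 0.03
    ph["smoking"] = rng.integers(0, 2, n)
    ph["bmi"] = rng.normal(26.5, 4.0, n).round(1)
    ph["alcohol"] = rng.gamma(2.0, 2.0, n).round(1)

    # --- polygenic scores and extreme groups --------------------------
    for s in ("prs_ea", "prs_iq", "prs_sz"):
        ph[s] = rng.standard_normal(n)
    n_cases = cfg.n_prs_cases
    if n_cases is None:
        n_cases = int(truth["high_risk"].sum())
    if n_cases < 1:
        n_cases = max(1, round(0.0266 * n))
    lo, hi = cfg.prs_quantile_band
    for s, tail in (("prs_ea", "low"), ("prs_iq", "low"), ("prs_sz", "high")):
        truth[f"{s}_extreme"] = assign_extremes(ph[s], n_cases, tail)
        truth[f"{s}_middle"] = middle_controls(ph[s], lo, hi)

    # --- outcomes -----------------------------------------------------
    age_c = ph["age"].to_numpy() - 45.0
    sex = ph["sex"].to_numpy(dtype=float)
    pc1 = ph["pc1"].to_numpy()
    exposures = truth.astype(float).assign(
        prs_ea_per_sd=ph["prs_ea"], prs_iq_per_sd=ph["prs_iq"])

    edu_cov = 0.30 * sex - 0.012 * age_c + 0.10 * pc1
    edu_level = _draw_ordinal(
        _planted_shift(cfg, "education", exposures) + edu_cov,
        cfg.education_probs, rng)
    ph["education_level"] = edu_level.astype(float)
    status = np.where(rng.random(n) < 0.02, "ongoing",
                      np.where(rng.random(n) < 0.02, "other", "completed"))
    ph["education_status"] = status
    miss = rng.random(n) < 0.01
    ph.loc[miss, "education_level"] = np.nan

    yrs_shift = _planted_shift(cfg, "education_years", exposures)
    ph["education_years"] = (13.5 + yrs_shift + 0.6 * sex - 0.03 * age_c
                             + rng.normal(0, 2.5, n)).round(1)

    inc_cov = (0.15 * sex + 0.005 * age_c + 0.08 * pc1
               + 0.10 * (ph["household_size"].to_numpy() - 2))
    income = _draw_ordinal(_planted_shift(cfg, "income", exposures) + inc_cov,
                           cfg.income_probs, rng)
    ph["household_income"] = income.astype(float)
    ph.loc[rng.random(n) < 0.02, "household_income"] = np.nan

    # health latent: higher = better self-reported health
    hl_cov = -0.020 * age_c + 0.05 * sex
    health_good = _draw_ordinal(
        _planted_shift(cfg, "health", exposures) + hl_cov,
        cfg.health_probs, rng)
    ph["subjective_health"] = (6 - health_good).astype(float)
    ph.loc[rng.random(n) < 0.01, "subjective_health"] = np.nan

    # SNPD diagnoses (binary logistic)
    base = math.log(cfg.snpd_prevalence / (1 - cfg.snpd_prevalence))
    eta = (base + _planted_shift(cfg, "snpd", exposures)
           + 0.30 * (ph["log_age"].to_numpy() - math.log(45)) + 0.10 * sex)
    any_snpd = rng.random(n) < 1 / (1 + np.exp(-eta))
    pheno_split = rng.choice(["ID", "SCZ", "EPI", "BD", "CBD", "PDD"], n,
                             p=[0.10, 0.22, 0.42, 0.14, 0.06, 0.06])
    for p in ("ID", "SCZ", "EPI", "BD", "CBD", "PDD"):
        ph[p] = any_snpd & (pheno_split == p)
    ph["MDD"] = rng.random(n) < cfg.mdd_prevalence
    ph["any_snpd"] = any_snpd

    # Charlson comorbidity index (Poisson count)
    cci_eta = (math.log(cfg.cci_mean)
               + _planted_shift(cfg, "cci", exposures) + 0.015 * age_c)
    ph["cci"] = rng.poisson(np.exp(cci_eta))

    # mortality: exponential hazard + administrative censoring
    rate = cfg.death_base_rate * np.exp(
        _planted_shift(cfg, "mortality", exposures)
        + 0.035 * age_c + 0.25 * sex)
    t_event = rng.exponential(1 / rate)
    t_censor = rng.uniform(*cfg.followup_years, n)
    ph["follow_time"] = np.minimum(t_event, t_censor).round(3)
    ph["death"] = (t_event <= t_censor).astype(int)

    calls = (simulate_cnv_landscape(truth[list(CNV_CLASSES)],
                                    cfg.background_rate, rng)
             if with_calls else None)

    return SyntheticBundle(
        cohort=cfg.cohort, config=cfg, phenotypes=ph, truth=truth,
        calls=calls, regions=fixture_regions(), genes=fixture_genes(),
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle in the standard input formats the pipeline consumes
    (PennCNV rawcnv dialect, BED region files, gene TSV, phenotype/truth
    TSVs). Returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if bundle.calls is not None:
        paths["calls"] = out / "calls.rawcnv"
        write_cnv_calls(bundle.calls, paths["calls"], "penncnv_rawcnv")
    for key, rs in bundle.regions.items():
        paths[f"regions_{key}"] = out / f"{key}.bed"
        write_region_bed(rs, paths[f"regions_{key}"])
    paths["genes"] = out / "genes.tsv"
    write_gene_models(bundle.genes, paths["genes"])
    paths["phenotypes"] = out / "phenotypes.tsv"
    bundle.phenotypes.to_csv(paths["phenotypes"], sep="\t")
    paths["truth"] = out / "truth.tsv"
    bundle.truth.to_csv(paths["truth"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# named scenarios


def _single_effect(name, exposure, outcome, beta, freq_overrides,
                   n_samples=20_000, **kw) -> ScenarioConfig:
    freqs = {c: 0.0 for c in CNV_CLASSES}
    freqs.update(freq_overrides)
    return ScenarioConfig(name=name, n_samples=n_samples, class_freqs=freqs,
                          planted={(exposure, outcome): beta},
                          any_high_risk_freq=None, **kw)


def scenario(name: str, n_samples: int = 20_000) -> ScenarioConfig:
    """Named study conditions.

    ``null``: default CNV landscape, no planted effects.
    ``paper_calibrated``: default landscape with every headline effect
        planted at its reported point estimate.
    ``education_highrisk``: high-risk carriers at 2.66% with the education
        ordered-logit effect planted at OR 0.77.
    ``education_prs_ea``: PRS-extreme groups frequency-matched to 2.66%
        carriers; education effect of the low-EA extreme planted at OR 0.31.
    ``education_years_per_sd``: +0.84 years of education per +1 SD of the
        EA score (linear).
    ``mortality_prs_ea``: hazard ratio 1.55 for the low-EA extreme.
    ``income_assoc_cnv``: income-associated CNV carriers at 0.5% with the
        income ordered-logit effect planted at OR 0.50.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; one of {sorted(SCENARIOS)}")
    return replace(SCENARIOS[name], n_samples=n_samples)


_HR_FREQ = {"large_del": 0.0266}  # single-class stand-in at the combined
                                  # high-risk carrier frequency

SCENARIOS: dict[str, ScenarioConfig] = {
    "null": ScenarioConfig(name="null"),
    "paper_calibrated": ScenarioConfig(name="paper_calibrated",
                                       planted=PAPER_CALIBRATED_EFFECTS),
    "education_highrisk": _single_effect(
        "education_highrisk", "high_risk", "education", math.log(0.77),
        _HR_FREQ),
    "education_prs_ea": _single_effect(
        "education_prs_ea", "prs_ea_extreme", "education", math.log(0.31),
        _HR_FREQ),
    "education_years_per_sd": _single_effect(
        "education_years_per_sd", "prs_ea_per_sd", "education_years", 0.84,
        _HR_FREQ),
    "mortality_prs_ea": _single_effect(
        "mortality_prs_ea", "prs_ea_extreme", "mortality", math.log(1.55),
        _HR_FREQ),
    "income_assoc_cnv": _single_effect(
        "income_assoc_cnv", "income_assoc", "income", math.log(0.50),
        {"income_assoc": 0.0050, "large_del": 0.0266}),
}
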