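# Methods

## Problem and design

Rare copy-number variants (CNVs) that overlap known syndrome regions,
delete dosage-sensitive genes, or are simply very large are conventionally
treated as high-impact findings. Most carriers in the general population,
however, never receive a diagnosis of a severe neurological or psychiatric
disorder (SNPD). This package implements a comparison design that puts such
"high-risk" CNV carriage on the same footing as the extreme tail of common
polygenic variation: for each cohort, the number of individuals at the
extreme of a polygenic score (PRS) distribution is matched to that cohort's
high-risk CNV carrier count, and both exposures are run through the same
battery of outcome regressions, with cohort results pooled by
heterogeneity-gated meta-analysis.

The underlying population data (two Finnish cohorts of roughly 23,000 and
4,900 participants) are access-controlled, so the package ships a
synthetic-cohort generator that reproduces the statistical structure of
such data and lets every pipeline stage be exercised — and its estimators
validated by planted-effect recovery — without any external download.

## CNV call QC

Calls enter as PennCNV-style text (1-based inclusive, converted on read) or
BED-like TSV (0-based half-open, the internal canonical convention
throughout). The QC stages, in default order:

1. **Filter**: keep calls with ≥ 10 supporting probes and length ≥ 100 kb
   (both inclusive).
2. **Merge**: adjacent calls with the same copy-number state for the same
   sample and chromosome are joined when the adjoining gap is at most 20%
   of the full joined span. Merging is applied left-to-right on
   position-sorted calls and iterated to a fixpoint, so chains collapse
   deterministically and the result is independent of input order.
   Overlapping same-state calls merge unconditionally with a warning; a
   merged call's probe count is the sum of its constituents (recorded for
   transparency, not re-filtered).
3. **Artefact flagging**: a call is set aside when ≥ 50% of it is covered
   by the union of HLA/immunoglobulin regions, or when it lies within
   500 kb (edge-to-edge) of a telomere or centromere region.
4. **Exclusion list**: manual plot curation is replaced by an explicit,
   reproducible list of (sample, chrom, start, end) keys.

Whether filtering precedes merging is configurable (`run_qc(order=...)`);
filter-first is the default. All "at least"/"at most" thresholds are
inclusive. Chromosome-label style mismatches ("chr1" vs "1") raise an
error rather than silently contributing zero overlap.

## CNV classes

Each QC-passing call is tested against every rule; one call may belong to
several classes and one carrier may hold several calls:

* **DECIPHER CNV** — ≥ 50% of the call covered by the union of syndrome
  regions. Dosage type is ignored by default (carrier tables group these
  without a del/dup split); a strict mode requires the region's dosage
  annotation to match.
* **ID gene deletion / high-pLI gene deletion** — a deletion touching
  (≥ 1 bp) at least 50% of the exons of an ID-causal gene, or of a gene
  with pLI ≥ 0.95. The exon-count reading ("50% or more of the exons") is
  isolated in one predicate (`exon_hit_fraction`) so the alternative
  exonic-sequence-fraction reading would be a one-line change. Missing pLI
  is treated as not intolerant.
* **Large deletion / duplication** — length strictly greater than 1 Mb.
* **Phenotype-associated CNVs** (educational-attainment, household-income,
  medical-consequence loci) — ≥ 50% of the call within a listed locus
  *and* matching dosage type. These lists are inputs; the matching rule is
  this package's choice.

**High-risk** is the OR of the first five classes; associated-locus classes
are tracked separately and do not confer high-risk status.

## PRS groups

Scores are z-standardized within cohort. "Extreme cases" are the n most
extreme individuals in the relevant tail (low tail for attainment-type
scores, high tail for liability scores), with n frequency-matched to the
cohort's high-risk carrier count. Controls are the middle 20–80% band,
selected by rank: with ascending ranks r = 1..N (ties broken by sample id),
controls satisfy ceil(0.2·N) < r ≤ floor(0.8·N). This boundary rule
reproduces the reference control-group sizes 13,831/23,053 and 2,937/4,895
exactly and is rank-invariant under monotone transforms of the score; the
band is configurable.

## Derived phenotypes

* **SNPD status**: per-phenotype flags (ID, SCZ, EPI, BD, MDD, childhood
  behavioural, psychiatric-development) from a user-supplied
  code-to-phenotype map; `any_snpd` excludes depression by design.
* **SES/health grouping**: group 1 (low SES, poor health) requires
  subjective health "average" (3) or worse AND education at
  lower-secondary level or lower AND income ≤ 5 of 9; group 3 requires
  health average or better AND upper-secondary education or higher AND
  income ≥ 5. Income 5 appears in both clauses as stated; the education
  clauses alone force disjointness, and the rules are implemented
  literally. Students, participants over 65, and records missing any
  component are excluded first.
* **Charlson comorbidity index**: sum of positive integer weights over
  distinct conditions. The registry-specific 20-phenotype mapping behind
  the reference analysis is not published; the classic Charlson weight
  table ships as a labelled default and any mapping can be supplied.
* **Eligibility filters** per analysis (education excludes "ongoing"/
  "other"/missing; income and health exclude missing outcomes; mortality
  and comorbidity require follow-up data), each with a per-reason
  exclusion report that sums back to the input count.

## Regression battery

Six families, all maximum likelihood: logistic, proportional-odds ordered
logit, linear, Cox proportional hazards (right-censored), Poisson, and
multinomial logit with the intermediate SES group as reference (two
contrasts: 1 vs 2 and 3 vs 2). Effects are reported for the exposure term
on the log scale with Wald 95% CIs exponentiated for ratio families;
`exp(estimate)` is the reported OR/HR/IRR to machine tolerance. Covariate
presets mirror the reference analyses: SNPD models use log-age, sex, PCs
1–10 and enrollment year; education ordered-logit uses age, sex, PCs;
years-of-education adds the baseline survey year; income adds household
size (with an adjusted-for-education variant); subjective health uses age,
sex, PCs; the comorbidity Poisson model adds enrollment year; Cox mortality
uses age, sex, PCs with an optional lifestyle block (smoking, BMI,
alcohol). Subjective health is stored 1 = good .. 5 = poor and modelled on
the reversed scale so OR > 1 means better reported health. Age enters
untransformed except in the SNPD models, where it is log-transformed.
Bonferroni adjustment is `min(1, m·p)` with the family size m an explicit
configuration value.

The ordered-logit fit subclasses statsmodels' `OrderedModel` only to add
the analytic cumulative-logit score; parameters, likelihood, threshold
reparameterization and inference are statsmodels'. (The parent
differentiates numerically, which dominated fit time on cohort-sized
tables.) Non-convergence and separation are reported on the result object
(`converged=False` plus a note), never as a silent number; a zero-variance
exposure is an error.

## Meta-analysis

Per-cohort log-scale estimates are pooled by inverse variance. Cochran's
Q, I² = max(0, (Q − df)/Q)·100 and DerSimonian–Laird τ² quantify
heterogeneity. The gate defaults to I² > 50%: above it, pooling switches
to random effects with weights 1/(se² + τ²); at τ² = 0 the two models
coincide exactly. The I² threshold is configurable and a Q-test p-value
gate is available, since the precise "considerable heterogeneity" rule in
the reference analysis is not public; 50% was chosen because the two
reference results flagged as heterogeneous sit just above it (I² ≈ 60%).

## Synthetic generator

Carrier structure: with the default calibrated frequencies, high-risk
carriage is drawn carrier-first — a sample is a carrier with probability
2.49% (3.49% for the birth-cohort-style preset) and its classes are then
sampled in
proportion to the per-class frequencies, with a second class added at the
rate implied by the ratio of the class-frequency sum to the union
frequency (≈ 1.23 classes per carrier). This reproduces both the union and
the per-class carrier frequencies of the reference tables, which an
independent-Bernoulli scheme cannot (it inflates the union to ~3.0%).
Low-frequency classes are slightly over-represented in second draws
(without-replacement sampling); the distortion is below sampling noise at
cohort sizes. Single-effect recovery scenarios instead set one class
directly at the stated exposure frequency with independent draws.

Each true class flag materializes as one template call constructed to
satisfy exactly its rule on a four-chromosome synthetic genome (~36 Mb
total); background calls (Poisson, mean 0.65/sample; sizes 100 kb plus an
exponential tail capped at 350 kb, so most are ≤ 250 kb) are placed in
zones spaced so that no pair can ever satisfy the merge rule or touch a
classification region. QC + classification therefore recover the planted
labels exactly, which the round-trip tests assert.

Outcomes are drawn from the same families the battery fits: ordinal
outcomes from a latent-logistic proportional-odds model (fixed thresholds
at the logistic quantiles of the base category probabilities, planted
effects and modest covariate effects as latent shifts); binary outcomes
from logistic models; counts from Poisson; survival from exponential
hazards with uniform administrative censoring at 15–25 years. PRS are
independent standard normal. Outcome correlation is induced only through
shared exposures and covariates — no residual copula — which is the
simplest structure consistent with the analysis models and makes
planted-parameter recovery well-defined; it is noted as extensible.

What the generator does *not* emulate: real linkage disequilibrium or
genotype-level data, de-novo vs inherited CNV status, ascertainment and
participation bias, registry coding noise, correlated PRS, and residual
dependence between outcomes. Passing recovery tests therefore demonstrate
estimator correctness under the assumed model families and the study's
sampling design, not robustness to real-data violations of those
assumptions.

## Numerical and design choices

* Internal coordinates are 0-based half-open everywhere; conversions only
  at IO boundaries, so `length = end − start` uniformly.
* Ties in PRS ranking are broken by sample id (real-valued scores make
  ties measure-zero; determinism matters for reproducibility).
* The gap fraction in merging is computed against the candidate joined
  span, and merging iterates to a fixpoint; both choices make the result
  order-independent.
* Recovery experiments use 100 replicates of N = 20,000 (replicate r uses
  seed base + r), reporting the mean on the ratio scale for log-link
  families. The replicate SD, not the per-fit SE, defines the Monte-Carlo
  tolerance (four standard errors of the replicate mean).
* Test-suite simulations use smaller cohorts (400–1,500 samples) for the
  structural and property tests, and 500 replicates of n = 400 for type-I
  calibration at α = 0.05 with a ±3 binomial-SD acceptance band.

## Known limitations

* The multinomial SES-group stage fits per cohort; its meta-analysis
  treats each contrast as an independent log-OR (no cross-contrast
  covariance).
* The merged-call probe count is a sum of constituents, which over-counts
  probes in overlapping constituents.
* The generator's education-years outcome is Gaussian with a fixed 2.5-yr
  residual SD, not the mixture of degree-specific durations real cohorts
  show.
* Eligibility filters assume the declared column schema; there is no
  schema-inference for arbitrary phenotype files.
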