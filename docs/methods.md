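# Methods

This note documents the statistical procedures `admixfine` implements, the
generative model behind its synthetic admixed cohorts, the numerical
choices, and what the shipped validation experiments do and do not
demonstrate.

## Study setting and model

The pipeline targets case-control fine-mapping of established GWAS risk
regions in a two-way admixed population.  Population 1 plays the role of
the ancestry in which index signals were discovered ("European-like");
population 2 the other ancestral component ("African-like").  Local
ancestry at a position is the expected number of population-1 chromosomes
carried (continuous in [0, 2]); global ancestry is summarized by principal
components of the standardized genotype matrix.

Association is modelled by unconditional logistic regression

> logit P(case) = β₀ + β·dosage + covariates (age, study indicators, top-K
> eigenvectors, region-average local ancestry)

with the per-allele test the 1-df Wald chi-square (β/SE)².  Imputed
variants enter as continuous dosages; Rsq (observed/expected dosage
variance) below 0.3 excludes a variant from analysis.  Both local and
global ancestry appear as covariates because admixture induces confounding
between ancestry-differentiated allele frequencies and any
ancestry-associated disease risk; local ancestry absorbs the region-level
component that eigenvectors miss.

### Two-tier significance and stepwise selection

Candidates inside a ±250 kb window (extended to cover a containing D′
block) are partitioned into the *index-correlated set* (r² ≥ 0.2 with an
index signal) and *novel* variants.  Correlated candidates are judged at
α_a = 0.05 over the number of greedy tags (r² ≥ 0.8) needed to capture the
correlated set — by default the cross-region average count, which yields
one shared threshold on the order of 0.004; a per-region mode is provided
because both conventions are defensible.  Novel
candidates are judged at α_b = 0.05 over the total tag count needed to
capture all common alleles (MAF > 0.05) across regions, on the order of
5.6×10⁻⁶ for ~9,000 tags.

Stepwise selection is forward with backward elimination after each entry
(entry threshold = retention threshold); "stepwise" alone does not fix a
direction, and this bidirectional form matches keep-in-the-final-model
semantics.  A forward-only switch is provided.  Missing hard
calls are mean-filled inside stepwise so the sample size is preserved;
single-variant tests default to complete cases (configurable), since
practice varies on mean-filling single-SNP models.
Ties on entry p-value break by smaller p, then lower genomic position.
Candidates with r² = 1 to a selected variant are skipped as collinear.  The
dense multi-signal scan restricts the candidate pool to variants with
single-SNP p < 0.05 and retains at p < 0.001 in the multivariate model.

The stepwise covariate set defaults to the *first* eigenvector while
single-variant tests default to the top 10 — an inconsistency inherited
from the procedure being reproduced, deliberately left configurable rather
than silently reconciled (`PipelineConfig.n_eigenvectors` vs
`stepwise_eigenvectors`).

### Risk score and familial risk

The score is the unweighted sum of risk-allele dosages over the score
variants, with a missing genotype contributing 2 × (control RAF) — its
expected value.  Quartile cutpoints come from the control distribution
using type-7 (linear-interpolation) quantiles; printed one-decimal
cutpoints in this literature imply an interpolating convention, and one
convention must be fixed.  Stratified quartile ORs use the
family-history-negative bottom quartile as the common reference cell.

The familial-risk decomposition takes the allele count as approximately
normal, with first-degree-relative count correlation r = 0.5 under
independent inheritance, and computes m_rel = m₀(1−r²) + m₁r²,
Δ = m_rel − m₀, ρ_score = exp(ln λ · Δ), f = (ρ_score−1)/(ρ_obs−1).  Note
the relatives' mean weights the case mean by r² = 0.25 even though the
count correlation is r = 0.5; the calculation is implemented exactly as
conventionally printed, with r exposed as a parameter.  A ρ-weighted
conditional mean (weight r rather than r²) would be the textbook
normal-theory regression toward the case mean; the package computes the
printed form and leaves the alternative to the caller via `r`.  Results are
reported at full precision and through the printed 2-decimal rounding path
(ρ_score rounded before the fraction), which is what reproduces "~11%"
digit for digit.

### Relatedness

IBD sharing probabilities (Z0, Z1, Z2) come from the method-of-moments
IBS decomposition with allele frequencies estimated from the full
post-filter sample (cases included; controls-only is a parameter).  "Within
1 SD" of a relationship's expected Z vector is operationalized as a single
configurable per-component scale (default 0.1), which reproduces the
rule's behaviour without replicating PLINK internals.  In an admixed sample the moment estimator is
biased toward apparent relatedness for ancestry-similar pairs because it
assumes homogeneous allele frequencies; truly related pairs remain well
separated, but the default classification scale should not be tightened
much below 0.1.  Pruning removes the maximum-degree node of the related
graph repeatedly, with seeded random tie-breaks (covering the
isolated-pair case).

## Synthetic data generator

The generator produces what the pipeline needs to be falsifiable: known LD,
known local ancestry, known effects, known relationships.

* **Allele frequencies.** A shared ancestral frequency (uniform on
  [0.1, 0.9] by default) diverges into the two panels by a Balding-Nichols
  Beta draw with parameter F (default 0.15, the CEU-YRI range), giving
  descendant variance F·p(1−p).
* **LD.** Variants are partitioned into blocks (default 2–6 variants);
  each block carries 2–8 founder haplotypes with Dirichlet weights, and
  pool haplotypes copy a founder per block, independently across blocks.
  Founder alleles are assigned by a cumulative-weight threshold
  construction whose straddling founder is randomized so that the expected
  pool frequency equals the Balding-Nichols draw exactly.  This yields high
  within-block LD with deterministic control; it is *not* a coalescent and
  makes no claim to realistic LD decay.  Engineered fixtures (e.g. the
  ancestry-asymmetric index/causal pair) use `panel_from_founders` with
  explicit haplotype classes and per-population weights.
* **Admixture.** Each individual draws an admixture proportion from
  Beta(θν, (1−θ)ν) (θ = 0.2, ν = 10 by default; ν = None fixes θ).  Each
  haplotype is a mosaic: ancestry-switch events are Poisson along the
  variant-index coordinate (genetic-map realism is out of scope) and at
  each event ancestry is *resampled* Bernoulli(θᵢ), which keeps the
  marginal at θᵢ; recorded switch counts therefore follow the configured
  Poisson rate exactly, while observable ancestry transitions are a thinned
  subset (a resample may land on the same ancestry).  Emitted local
  ancestry is the true population-1 chromosome count.
* **Emission.** Typed variants emit integer dosages with missing calls at
  the configured rate (default 1%).  Imputed variants (default 30%) emit
  true dosage + Gaussian noise clipped to [0, 2]; because clipping
  attenuates noise, the noise SD is calibrated per variant by bisection so
  the realized squared correlation with the true dosage matches the target
  Rsq (drawn uniform on [0.25, 1] so the Rsq < 0.3 filter has work to do).
* **Phenotypes.** logit P(case) = logit(prevalence) + Σβᵢgᵢ (centered) +
  0.02·(age−65) + study offsets + ln(1.55)·FH.  Family history is Bernoulli
  (10% baseline, optionally score-dependent) and missing in 10% of cases /
  16% of controls; severity labels attach to cases only.  Case-control
  ascertainment is rejection sampling in batches with a bounded attempt
  budget (default prevalence 0.12).  Causal per-allele ORs in configs are
  kept in the 1.05–1.4 range typical of common risk alleles.
* **Relatives.** MZ copies both haplotypes; parent-offspring and sibling
  samples receive recombined transmissions (Poisson crossovers, default 1
  per transmission for a single region; the relatedness experiments use 30
  to emulate genome-wide averaging, otherwise single-pair realized IBD is
  far from its expectation).  Transmission masks give exact IBD truth.

Same configuration + seed ⇒ byte-identical output; every stochastic call
flows from one `numpy.random.Generator`.

**What passing tests do not show about real data:** the generator has no
LD decay with distance, no recombination map, no genotyping batch effects,
no imputation-model misspecification beyond Gaussian noise, and phenotypes
follow the fitted model family exactly — so the experiments validate the
*procedures* (calibration, recovery, rule fidelity), not robustness to
model misspecification in real cohorts.

## Validation experiments (problem sizes)

Sizes were chosen as the smallest at which the phenomena of interest are
comfortably resolved:

* **Null calibration** — 1,000 cases / 1,000 controls, 1,000 variants.
  Variants are simulated as single-variant blocks (mutually independent)
  because the binomial bound on the count of p < 0.05 tests presumes
  independent tests; LD would inflate the count's variance without changing
  the per-test level being measured.  Heterogeneity uses Cochran's Q over
  4 study strata at 76 common variants (MAF ≥ 0.2, matching the common
  GWAS-hit panel such tests are run on in practice).
* **Proxy recovery** — 100 replicates of 3,000/3,000 at 80:20 admixture
  (80% from the low-LD ancestry).  The index/causal haplotype classes are
  set so r²(index, causal) = 0.90 on population-1 haplotypes and 0.05 on
  population-2; a replicate succeeds when stepwise selection (α = 0.004,
  age/study/local-ancestry adjusted) returns the causal variant or a proxy
  with higher admixed-sample r² to it than the index.
* **Score recovery** — 100 replicates of 3,400/3,300 with counts over 27
  unlinked variants and true per-allele OR 1.17; checks CI coverage and
  Q1→Q4 monotonicity of quartile ORs.
* **Relatedness** — 80 samples, 2,500 independent typed variants,
  injected MZ/parent-offspring pairs, crossover rate 30.

## Numerical choices and degenerate inputs

Logistic fits use Newton-Raphson (statsmodels) with separation surfaced as
an explicit error or flag (a Firth-style fallback is deliberately not the
default).  Constant dosages are skipped with a reason; constant covariates
are dropped (they are collinear with the intercept and must not move any
estimate).  PCA uses SVD with eigenvector sign fixed by the first sample's
loading; monomorphic variants are dropped before standardization; requests
beyond rank raise.  D′ haplotype frequencies come from the standard
genotype-table EM (only the double-heterozygote class is ambiguous),
tolerance 1e-10, max 500 iterations.  r² thresholds are inclusive (≥) at
the stated cut-offs.  Greedy tagging breaks ties by genomic position for
determinism; perfect-proxy conditioning returns β = 0, p = 1 with a
collinearity flag rather than a singular fit.  Coordinates are 1-based
closed intervals throughout (VCF convention), and fine-mapping windows are
[pos − 250,000 + 1, pos + 250,000].

## Known limitations

Single-marker tagging only (multi-marker tagging is not implemented);
no Bayesian fine-mapping or credible sets; no sex checks (requires array
intensities); IBD estimation ignores ancestry stratification (see above);
the familial-risk decomposition inherits the normality and r²-weighting
assumptions of the conventional calculation; the generator's LD model is a
design tool, not a population-genetic simulation.
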