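# Methods

## Model and estimator

The package implements two-sample summary-statistic Mendelian randomization
(MR). The causal diagram is the standard instrumental-variable one: genetic
variants G_j affect an exposure X; X may causally affect a binary disease D;
an unobserved confounder U affects both X and D; the instruments are valid if
they affect D only through X and are independent of U.

Given per-allele summary statistics (γ̂_j, σ̂_γj) for the SNP-exposure
associations and (Γ̂_j, σ̂_Γj) for the SNP-outcome log-odds ratios, estimated
in non-overlapping samples, each SNP yields the Wald ratio β̂_j = Γ̂_j/γ̂_j
with first-order standard error σ̂_Γj/|γ̂_j| (uncertainty in γ̂_j is ignored,
the classical summary-data convention; no heterogeneity inflation is applied
— fixed-effect IVW only). The pooled estimate is the precision-weighted mean
of the ratios, algebraically identical to the weighted through-origin
regression of Γ̂ on γ̂ with weights σ̂_Γj⁻². Estimation is always done per
exposure unit and rescaled for reporting: OR per SD = exp(β̂·s) with 95% CI
exp((β̂ ± z·se)·s), z = Φ⁻¹(0.975) = 1.959964, and a two-sided normal
p-value for β̂/se (invariant to the positive scale factor s). Binary
exposures are reported per unit increase in their log-odds (s = 1).

Cross-cohort combination happens at the per-SNP level *before* MR: outcome
log-odds ratios from the cohorts are pooled by fixed-effect inverse-variance
meta-analysis after orienting allele labels to a common reference. Cochran's
Q per SNP is computed and logged but never used as a filter. A SNP typed in
only one cohort passes through unchanged.

Published rows given as OR with 95% CI are ingested by back-derivation:
log OR = ln(OR), se = (ln CI_high − ln CI_low)/(2·1.959964). Note that
quantities re-derived from *printed* (rounded) ORs and CIs inherit that
rounding: a p-value recomputed from a table row can differ from the printed
p-value in the last digit, because the published p came from unrounded
estimates. Tests that compare against printed rows therefore work at printed
precision (propagating half-ulp rounding boxes) rather than asserting exact
digit matches.

## Sensitivity analyses

Three pleiotropy diagnostics are provided. (1) Each SNP's outcome
association is screened with a two-sided normal p-value for Γ̂_j/σ̂_Γj
against a Bonferroni threshold α = family_α / n_tests (e.g. 0.05/49 for a
49-SNP set; a 55-test scan family gives 9.1×10⁻⁴). |z| is invariant to
allele re-orientation, so the screen does not depend on the harmonization
sign convention. (2) The full IVW pipeline is rerun with flagged or named
variants excluded and reported next to the baseline. (3) Leave-one-out
estimates, one per omitted SNP, plus a per-SNP (γ̂, Γ̂, σ̂_Γ) scatter export;
plotting is deliberately left to the user so no analysis output depends on
rendering.

## Harmonization conventions

Allele matching is by literal label comparison: identical pairs pass
through, exactly swapped pairs negate the outcome effect, anything else is
kept but marked `dropped_mismatch` and barred from estimation. Strand
inference from allele frequencies is out of scope, so palindromic (A/T, C/G)
SNPs are governed by a policy switch: `trust` (default) takes labels at face
value — appropriate for curated instrument lists whose strand was resolved
upstream — while `strict` drops them. After matching, every estimable record
is oriented so the effect allele is the exposure-increasing allele
(γ ≥ 0, outcome sign flipped in tandem); the IVW estimate is invariant to
this convention, which exists to make scatter and leave-one-out outputs
directly comparable across SNPs. Instruments absent from the outcome table
are dropped with a logged warning (no LD-proxy lookup — that would require
an external reference panel); zero overlap is a hard error.

QC rules for outcome genotyping follow the usual case-control array
thresholds, with inclusive call-rate/MAF bounds and strictly-exceeded HWE
bounds: pass iff [(call rate ≥ 0.95 and MAF ≥ 0.05) or (call rate ≥ 0.99 and
MAF < 0.05)] and HWE p > 10⁻¹² in cases and > 10⁻⁷ in controls and, for
imputed variants, imputation R² ≥ 0.6. Fail reasons name the first violated
rule in that order.

## Genetic-score confounder scans

The "no confounding" assumption is probed with unweighted genetic scores:
per individual, the count of exposure-increasing alleles over the instrument
SNPs (orientation taken from the sign of the instrument table's γ; missing
dosages are an error by default, with optional per-SNP mean imputation).
Each trait in a panel is regressed on the score — OLS for quantitative
traits, logistic regression for binary traits, no covariates (the score is
the sole predictor) — and judged against a Bonferroni threshold over the
whole scan family. The family size of 55 used in examples corresponds to 5
scores × 11 traits; a binary trait observed in a single class is skipped
with a warning. Score scans use statsmodels fits directly, which doubles as
an independent cross-check of the hand-vectorised logistic solver used
inside the simulator (the two are compared in the test suite).

## Synthetic-data generator

`summr.simulate` draws complete two-sample studies with known truth:

- genotypes g_ij ~ Binomial(2, f_j) (Hardy-Weinberg, independent SNPs — no
  LD, matching the use of distinct curated loci as instruments);
- exposure X_i = Σ_j γ_j g_ij + a·U_i + ε_i with U, ε standard normal and
  the residual sd chosen so var(X) ≈ 1, i.e. the exposure is expressed in
  SD units;
- disease D_i ~ Bernoulli(expit(b0 + β·X_i + d·U_i + Σ_j π_j g_ij)), where
  β is the conditional causal log-odds per exposure unit and π_j optional
  direct (pleiotropic) SNP effects;
- the exposure GWAS is a population cohort (per-SNP marginal linear
  regressions, closed-form and vectorised); the outcome GWAS draws an
  *independent* population (separate RNG streams per role and cohort label —
  two-sample independence holds by construction), accumulates it into case
  and control pools of the requested sizes, and fits per-SNP logistic
  regressions of status on dosage;
- the trait panel for confounder scans contains 11 traits (9 quantitative:
  age, age at menarche, age at menopause, BMI, fasting glucose, fasting
  insulin, 30-minute insulin, physical activity, energy intake; 2 binary:
  education, smoking at 45% and 30% prevalence). The designated exposure
  trait is the built exposure mapped onto its registry mean/SD; optional
  per-allele links plant genetic effects on further quantitative traits
  (e.g. a secretion-score → fasting-glucose link); everything else is
  independent of genotype.

Per-SNP logistic fits use an exact Newton-Raphson MLE on each SNP's
aggregated 3×2 dosage-by-status table (sufficient for hard-call dosages),
vectorised across SNPs; it equals the individual-level statsmodels Logit
MLE to ~1e-6 (tested) and makes 500-replicate Monte-Carlo studies cheap.

Default design (the study scale all calibration results refer to): 36 SNPs,
allele frequencies U(0.1, 0.4), per-allele effects γ_j ~ U(0.02, 0.06) in
exposure-SD units (≈2% of exposure variance explained; mean single-SNP
F ≈ 30 at the default exposure-GWAS size), confounder loadings a = d = 0.3,
baseline log-odds −2, conditional causal effect β = 0.85, exposure GWAS
n = 50,000, outcome GWAS 1,287 cases / 8,273 controls, trait panel
n = 10,000. These sizes mirror a realistic insulin-exposure / cancer-outcome
two-sample study: a large population exposure GWAS, a modest case-control
outcome study, and a mid-sized population cohort for score scans.

### What the generator does *not* emulate

No linkage disequilibrium, population stratification, genotyping error,
imputation noise, sample overlap between the two samples, or assortative
mating. Passing calibration tests on this generator therefore demonstrates
the statistical machinery is correct under the model's own assumptions; it
does not certify robustness to LD-contaminated instrument sets, residual
stratification, or winner's-curse-inflated weights in real data.

## The estimand: marginal versus conditional odds ratios

With a binary outcome modelled by logistic regression, per-SNP GWAS
coefficients are *marginal* log-odds ratios: all risk variation other than
the SNP (the rest of the exposure, the confounder) is integrated out. Odds
ratios are non-collapsible, so summary MR identifies the population-averaged
causal log-OR per exposure unit, which is attenuated relative to the
conditional coefficient β whenever the remaining linear-predictor variance
is non-negligible; the two coincide under the null. At the default design
the conditional β = 0.85 corresponds to a marginal estimand of ≈ 0.733.

`marginal_causal_logor` computes this estimand analytically and from
scratch: per SNP, the three dosage-cell disease probabilities are
Gauss-Hermite integrals (81 nodes) of the logistic model over the remaining
linear predictor (approximately normal by the CLT over the other SNPs plus
the normal confounder and noise); the limiting GWAS coefficient is the
Hardy-Weinberg-weighted logistic projection onto (intercept, dosage); Wald
ratios are pooled with their limiting IVW weights. Logistic slopes are
invariant to outcome-dependent sampling, so the case-control scheme does not
enter. The analytic value is cross-checked in the test suite against a
brute-force mega-cohort oracle (600k individuals) and agrees within
Monte-Carlo error.

Calibration results are therefore stated against the marginal estimand:
95% CI coverage over 500 replicates at the default design falls in
[92.5%, 97.5%], and the type-I error of the IVW test over 500 null
replicates is ≈5% at α = 0.05. A small residual attenuation relative even
to the marginal estimand (≈2.7% at the defaults) is finite-sample
weak-instrument bias from noise in γ̂ and vanishes as the exposure-GWAS
sample grows. Users comparing recovered estimates to their design's
conditional β at large effect sizes should expect the non-collapsibility
gap; it is a property of the odds-ratio scale, not an estimator defect.

## Numerical choices and degenerate inputs

- 95% multiplier fixed at 1.959964 (not 1.96); p-values from the standard
  normal, not t.
- Newton solvers (per-SNP logistic, logistic projection) iterate to a
  step-size tolerance of 1e-12 with a 100-iteration cap; a singular
  information matrix (e.g. a monomorphic SNP) or non-convergence raises
  rather than returning garbage.
- Gauss-Hermite integration uses 81 probabilists' nodes; the integrand is a
  bounded sigmoid, for which this is far beyond the accuracy needed.
- `se_from_ci` accepts a zero-width CI but flags it degenerate (se = 0);
  estimators reject non-positive standard errors.
- Wald ratios are undefined at γ̂ = 0 and raise naming the SNP; exclusion
  reruns that would empty the instrument set raise; leave-one-out requires
  at least two SNPs.
- Display rounding (OR/CI to 2 decimals, p to 2 significant figures) is
  confined to `format_*` helpers and the `*_display` report; every stored
  value keeps full precision, and report TSVs serialise floats via `repr`
  so repeated runs are byte-identical.
- QC fail reasons are deterministic: the first violated rule in the fixed
  order call-rate/MAF, HWE cases, HWE controls, imputation R².
- The case-control sampler draws chunks (≥10,000 individuals) until quotas
  are met, capped at 200 chunks, and errors with advice to raise the
  baseline log-odds if the disease is too rare to yield the requested cases.

## Design choices where the design was open

- Meta-analysis is performed on per-SNP associations before MR rather than
  on per-cohort MR estimates: the pooled-then-estimate route uses each SNP's
  full cross-cohort precision and matches how multi-cohort outcome GWAS
  results are published.
- The Bonferroni screen runs on the pooled (META) outcome associations, the
  same statistics that enter estimation.
- Outcome tables may arrive either as (log OR, se) or as published
  (OR, CI_low, CI_high); both ingestion paths are first-class because
  curated instrument-outcome tables in the literature print the latter.
- Monte-Carlo problem sizes: the test suite uses 500 replicates each for
  coverage and type-I error (Monte-Carlo sd ≈1% at 95%/5%), and the
  acceptance script uses 300 each; both at the full default design scale.

## Known limitations

- First-order Wald-ratio weights ignore σ̂_γj, so weak instruments attenuate
  estimates toward the null; no Egger, weighted-median or modal estimators,
  no multivariable MR, no winner's-curse correction (all deliberately out of
  scope).
- No LD-proxy search: instruments missing from the outcome table are simply
  dropped (with a warning).
- Harmonization cannot rescue palindromic SNPs whose strand genuinely
  differs between tables; `strict` mode is the safe choice for
  non-curated inputs.
- The confounder scan is a power-limited screen, not proof of instrument
  validity; unmeasured confounders remain possible.
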