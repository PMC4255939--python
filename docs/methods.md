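# Methods

This note records the statistical models implemented by gxescreen, the
conventions and numerical choices behind them, what the synthetic-cohort
generator does and does not emulate, and the package's known limitations.

## Study design and data model

The unit of analysis is a subject-level case–control table: binary status
(1 = case), diploid genotypes at a small catalog of biallelic SNPs, binary
exposures, and continuous covariates. Genotypes are stored as unordered
allele pairs (``"AG"``, alleles sorted), so textual dialects (``A/G``,
``G|A``, ``AG``) and phase collapse to one representation. Three codings
are supported: codominant (three-level categorical, major-allele homozygote
as reference), dominant/carrier (≥ 1 risk allele), and additive (risk-allele
count).

Missing data are handled complete-case **per analysis**: each operation
drops subjects missing any variable it uses and reports the drop count.
This mirrors how per-SNP effective denominators arise in genotyping studies
with < 100% call rates and avoids imputation assumptions.

Clinical flags are derived only where absent: hypertension = SBP ≥ 140 mmHg
or DBP ≥ 90 mmHg or current antihypertensive treatment; hyperlipidemia =
fasting TC ≥ 200 mg/dL or LDL-C ≥ 130 mg/dL, with mmol/L measurements
converted at 38.67 mg/dL per mmol/L (configurable); BMI = weight/height²
(kg/m²). Explicit flags always take precedence.

## Descriptive comparisons

Continuous variables: two-sample *t* with the unequal-variance
(Welch/Satterthwaite) statistic by default. The pooled equal-variance form
is available behind a flag; reference studies in this design space follow
the SAS convention of reporting the pooled form when a preliminary
folded-F test is non-significant, so both are needed to reproduce printed
tables. Categorical variables: Pearson χ² on the r×c contingency table
with **no** continuity correction (Yates optional), expected counts from
the margins, df = (r−1)(c−1). p-values are reported to four decimals with
`<.0001` flooring.

## Hardy–Weinberg equilibrium

Tested in controls as a genotyping-quality check. The risk-allele
frequency p̂ is estimated from the genotype counts; expected counts are
(n p̂², 2 n p̂ q̂, n q̂²); the Pearson goodness-of-fit statistic is referred
to χ² with one degree of freedom (three classes, one estimated parameter),
no continuity correction. A monomorphic locus is an error, not χ² = 0.

## Odds ratios and logistic regression

Crude 2×2 odds ratios are cross-product ratios with Woolf (log-OR Wald)
intervals, `exp(ln OR ± 1.959964 · √(1/a + 1/b + 1/c + 1/d))`. If any cell
is zero the Haldane–Anscombe +0.5 correction is applied to all cells and
flagged; a double diagonal zero is non-estimable.

Logistic models are fitted by Newton–Raphson maximum likelihood
(statsmodels), with the covariance taken as the inverse observed
information. Before fitting, the design is checked for rank deficiency
(offending columns are named); diverging coefficients (|β| > 30) or a
perfect-separation condition raise a separation error rather than
returning meaningless Wald statistics. Single-SNP association emits the
codominant contrasts (het vs reference homozygote, risk homozygote vs
reference) from one three-level model and the carrier contrast from a
dominant model, each crude and adjusted; the default adjustment set is
age, sex, ethnicity, BMI, smoking and drinking.

## GMDR

For binary traits the GMDR score statistic is the residual
*s_i = y_i − p̂_i* from a logistic null model containing only the
adjustment covariates (intercept-only if none); with an intercept the
residuals sum to zero, so a positive score marks a subject more affected
than their covariates predict.

For a candidate combination of categorical factors (SNPs enter with three
genotype levels, clinical factors with two), training subjects are
cross-classified into cells. A cell is labelled **high risk** when its
mean training score exceeds the threshold (default 0; an exact tie is low
risk), **low risk** otherwise, and **unclassifiable** when no training
subject occupies it. Prediction accuracy on held-out subjects is
residual-mass weighted: of the total |s| mass in classifiable cells, the
fraction that is concordant (positive scores in high cells plus
non-positive scores in low cells). This weighting makes the sign rule the
per-cell optimum — a cell's best label is exactly the sign of its summed
score — and reduces to balanced accuracy when all |s_i| are equal. The
weighted form is one of several metrics used by GMDR implementations; it
is isolated behind `score_weighted_accuracy` so a count-based variant can
be swapped in.

Cross-validation is stratified by case status with K = 10 folds (sizes
within a stratum differ by at most one). Per combination: cells are
labelled on each 9/10 training split and accuracy measured on the held-out
tenth; the mean of the K testing accuracies ranks combinations. The
exhaustive search enumerates all subsets of each size from 1 to 5 and
reports the best per size; ties break lexicographically and are logged.
**Cross-validation consistency (CVC)** is the number of folds in which the
per-size winner also attains the best training accuracy among same-size
subsets. The **sign test** counts folds with testing accuracy strictly
above ½ (ties count against) and refers the count to the upper tail of
Binomial(K, ½); at K = 10 the attainable p-values are 1/1024 ≈ 0.0010,
11/1024 ≈ 0.0107, 56/1024 ≈ 0.0547, … The **permutation test** shuffles
case/control status, refits the covariate-only null model on the permuted
outcome (preserving covariate structure under the null), reassigns folds
and re-evaluates; `p = (1 + #{perm ≥ observed}) / (B + 1)` with B = 1000 by
default. Subjects missing any factor of a combination are dropped for that
combination only.

## Multiplicative and additive interaction

For a dominant-coded SNP G and binary exposure E, the joint-exposure model
codes the four (G, E) categories as indicators against the (G−, E−)
reference, plus covariates; exp(b1), exp(b2), exp(b3) are OR10, OR01, OR11.
Multiplicative interaction is the Wald test of the product term in a
main-effects-plus-product model.

Additive interaction on the odds-ratio scale:

- RERI = e^{b3} − e^{b1} − e^{b2} + 1, gradient (−e^{b1}, −e^{b2}, e^{b3});
- API = RERI/e^{b3} = 1 − (e^{b1} + e^{b2} − 1)e^{−b3}, gradient
  (−e^{b1−b3}, −e^{b2−b3}, (e^{b1}+e^{b2}−1)e^{−b3});
- S = (e^{b3} − 1)/((e^{b1} − 1) + (e^{b2} − 1)), with the CI built on
  ln S (gradient (−e^{b1}/(e^{b1}+e^{b2}−2), −e^{b2}/(e^{b1}+e^{b2}−2),
  e^{b3}/(e^{b3}−1))) and exponentiated so the interval stays positive.

Variances come from the delta method on the 3×3 covariance of
(b1, b2, b3) from the single joint fit (the Hosmer–Lemeshow construction,
as in Andersson's interaction spreadsheet); the normal multiplier is fixed
at 1.959964. API's interval is left untransformed. S is undefined when the
main-effect excesses cancel ((e^{b1}−1) + (e^{b2}−1) = 0); RERI and API are
still returned and the decision rule falls back to them. Additive
interaction is declared when 0 lies outside both the RERI and API
intervals **and** 1 lies outside the S interval (closed-interval
containment: a boundary hit counts as inclusion, hence no interaction).

The delta intervals are symmetric; the finite-sample sampling distribution
of RERI is right-skewed, so they differ from percentile-bootstrap
intervals at small n and converge as n grows (verified across
n ∈ {500, 2000, 8000} in the test suite).

## Synthetic cohort generator

The generator draws a latent population — per-SNP genotypes as two
independent Bernoulli(allele-frequency) draws (hence Hardy–Weinberg
proportions), independent binary exposures, normal age and BMI, binary
sex/ethnicity/smoking/drinking — assigns each subject
`P(case) = logistic(β0 + Σ βv·v + Σ βuv·u·v)` for declared variables and
pairwise products, realises status, and samples the requested numbers of
cases and controls without replacement (oversampling the population and
escalating the multiplier if a stratum is short). This mirrors fixed-size
hospital-based recruitment and gives exact group sizes without weighting.
All randomness flows through one explicit `numpy.random.Generator`.

The study-shaped defaults (`study_config`) emulate the motivating cohort:
502/308 group sizes; rs10757274 (risk allele G) with a control risk-allele
frequency near 0.42 and ~2% missing genotypes; rs6903956 (risk allele A)
near 0.08 with ~4.5% missingness; control-group T2DM prevalence near 24%
and smoking near 35%; and planted conditional odds ratios (1.60, 1.68,
4.38) for the carrier-only / T2DM-only / joint categories, i.e. a
super-additive (RERI = 2.10) but sub-multiplicative gene–environment
effect. rs6903956 carries no planted effect: its apparent crude
association in this design arises from confounding and vanishes under
adjustment, so a zero coefficient is the appropriate generative null.

The latent population is given a **rare disease** (intercept −5.3, ~8%
prevalence). This matters: sampled controls then approximate the source
population, so control genotypes stay in Hardy–Weinberg proportions
(rejection rate ≈ the nominal 5%). With a common latent disease the
selection of non-cases visibly distorts control genotype frequencies
whenever a genotype effect is planted — a real epidemiological phenomenon,
but not the regime of a hospital-based study of myocardial infarction.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population stratification, correlations among covariates and
exposures (smoking–sex, T2DM–BMI, …), measurement error, or continuous
outcomes. Passing tests therefore demonstrate correctness of the
estimators and calibration under independence, not robustness to the
dependence structures of real cohorts.

## Problem sizes used in the test suite

Simulation-based checks use sizes chosen to keep each property's Monte
Carlo error well inside its assertion band: 400 replicates for null
calibration of Wald p-values, 500 for Wald CI coverage of a planted
carrier log-OR at n = 810, 200 for delta-method RERI coverage at n = 2000,
100 for GMDR null-accuracy/permutation-uniformity at B = 99, and 200
regenerations for the control-group HWE rejection rate. Binomial
three-sigma bands around the nominal rates set the assertion limits.

## Known limitations

- **Sign-threshold pooling can be blind to secondary factors.** A GMDR
  cell is informative only if its mean score crosses the labelling
  threshold. When one factor carries a strong main effect, the cells of a
  correct two-factor model can all fall on the same side of the threshold
  as the strong factor alone; the pair's partition then collapses onto the
  one-factor split and its testing-accuracy margin over (strong factor +
  inert factor) pairs is near zero. In that regime, which pair wins the
  two-factor search is substantially noise-driven at n ≈ 800 even when a
  genuine interaction of moderate size (joint OR ≈ 4.4) is present; model
  selection should be read jointly with CVC, the sign test and the
  permutation test, not as evidence by itself.
- Wald/Woolf intervals and the delta method are first-order asymptotic;
  with sparse cells (any joint category under ~10 subjects) exact or
  bootstrap methods should be preferred.
- No multiple-testing correction is applied anywhere (matching the
  motivating design); the exhaustive GMDR search output is a screen, not a
  confirmatory analysis.
- The permutation test refits only the null model per replicate; covariate
  effects are assumed exchangeable under permuted status.
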