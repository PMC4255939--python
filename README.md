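# gxescreen

Gene–environment interaction analysis for case–control genetic association
studies: baseline descriptives, Hardy–Weinberg testing, crude and
covariate-adjusted logistic association, a from-scratch **generalized
multifactor dimensionality reduction (GMDR)** interaction screen, and
**additive-interaction** estimation (RERI / API / synergy index) with
delta-method confidence intervals.

The package targets the standard workflow of candidate-SNP case–control
studies of complex disease — the motivating design is a hospital-based
myocardial-infarction study of 502 cases and 308 controls genotyped at
rs10757274 (chromosome 9p21, near *CDKN2A/B*) and rs6903956 (6p24,
*ADTRP*), with type 2 diabetes, hypertension and hyperlipidemia as
candidate environmental factors and age, sex, ethnicity, BMI, smoking and
drinking as adjustment covariates. Because individual-level data from such
studies are rarely deposited, a first-class synthetic-cohort generator with
a configurable logistic disease model (including planted gene×environment
effects) makes every stage testable end to end.

## Methods at a glance

- **Descriptives** — Welch two-sample *t* (Satterthwaite df; pooled variant
  available) for continuous variables, Pearson χ² without continuity
  correction for categorical ones.
- **Hardy–Weinberg** — Pearson goodness-of-fit χ² with df = 1 in controls,
  allele frequency estimated from the genotype counts.
- **Association** — crude odds ratios as cross-product ratios with Woolf
  (log-OR Wald) 95% CIs; codominant and carrier (dominant) logistic models
  by maximum likelihood, crude and covariate-adjusted.
- **GMDR** — score residuals *s_i = y_i − p̂_i* from a covariate-only
  logistic null model; factor-combination cells pooled into high/low risk
  by the sign of the mean training residual; residual-mass-weighted
  balanced testing accuracy under stratified 10-fold cross-validation;
  cross-validation consistency; exact Binomial(K, ½) sign test; optional
  permutation test that refits the null model under shuffled status.
- **Interaction** — joint four-category logistic model
  `logit P = b0 + b1·[G+E−] + b2·[G−E+] + b3·[G+E+] + covariates`, product-term
  (multiplicative) Wald test, and additive-interaction indices

      RERI = OR11 − OR10 − OR01 + 1
      API  = RERI / OR11
      S    = (OR11 − 1) / ((OR10 − 1) + (OR01 − 1))

  with 95% CIs by the delta method on (b1, b2, b3) (log scale for S).

See `docs/methods.md` for assumptions, numerical conventions and known
limitations.

## Worked example

```python
import numpy as np
from gxescreen import (
    generate_study_fixture, genotype_counts, hwe_chi2_test,
    genotype_association, compute_score_residuals, factor_matrix,
    assign_cv_folds, search_models, fit_joint_exposure_model,
    additive_interaction,
)

cohort = generate_study_fixture(seed=1)        # 502 cases / 308 controls

hwe = hwe_chi2_test(genotype_counts(cohort, "rs10757274", "controls"))
assoc = genotype_association(cohort, "rs10757274")

scores = compute_score_residuals(
    cohort, ["age", "sex", "ethnicity", "bmi", "smoking", "drinking"])
factors = factor_matrix(cohort, ["rs10757274", "rs6903956"],
                        ["t2dm", "hypertension", "hyperlipidemia"])
folds = assign_cv_folds(cohort.status.to_numpy(), 10, np.random.default_rng(1))
search = search_models(factors, scores, folds, 1, 3)

model = fit_joint_exposure_model(cohort, "rs10757274", "t2dm")
add = additive_interaction(model)
```

Output (abridged):

```
cohort: 502 cases / 308 controls
control HWE rs10757274: chi2=0.152, p=0.696
adjusted carrier OR: 2.13 (1.51, 3.01), p=0.0000
 n_factors                              model  testing_accuracy   cvc  p_sign
         1                               t2dm            0.6006 10/10  0.0107
         2               hyperlipidemia, t2dm            0.6006  0/10  0.0107
         3 hyperlipidemia, hypertension, t2dm            0.6006  0/10  0.0107
OR10=1.89 OR01=2.00 OR11=4.69
RERI=1.80 (-0.18, 3.79); API=0.38; S=1.96
```

Reading it: the control genotypes are consistent with Hardy–Weinberg
equilibrium (χ² = 0.152, p = 0.70, a genotyping-quality check); carriers of
the G risk allele have about twice the adjusted odds of being a case; the
GMDR screen ranks T2DM-containing models highest (mean cross-validated
testing accuracy 0.60, significant by the exact sign test); and the joint
carrier×T2DM odds ratio (4.69) exceeds the sum of the separate excesses
(RERI = 1.80 > 0), pointing toward super-additivity, though this single
replicate's RERI interval narrowly includes 0.

The same pipeline runs from the shell:

```sh
gxescreen simulate --seed 1 --out cohort.tsv
gxescreen run --config run.yaml          # table1/hwe/association/gmdr/interaction reports
gxescreen interact --config run.yaml --snp rs10757274 --env t2dm
```

where `run.yaml` names the input table, the SNP catalog (name, risk and
reference allele), covariates, GMDR settings (folds, model sizes,
permutations) and the output directory; see `tests/test_pipeline_cli.py`
for a complete example.

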