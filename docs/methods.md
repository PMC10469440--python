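# Methods

## The problem

In epidemiological studies that profile the blood metabolome with untargeted
LC-HRMS, most designs afford a single biological sample per person. Whether a
single measurement reflects a person's usual level over months depends on how
the total variance of each metabolic feature splits into stable
between-person differences and everything else (assay noise plus short-term
biological fluctuation). The intraclass correlation coefficient (ICC) — the
fraction of total variance attributable to stable differences — quantifies
this per feature. Untargeted feature tables complicate the estimate in one
important way: many features are not detected in every sample, and a
nondetect is not a missing-at-random value but an observation known to lie
below the feature's limit of detection (LOD). Dropping nondetects or
substituting a fraction of the LOD biases variance components; this package
instead handles them in the likelihood.

## Measurement model

For a feature measured in sample *i* of subject *j* at center *k*, the
natural-log intensity is modelled as a three-level nested random-intercept
model:

    y_ijk = x_ijk' beta + u_k + u_jk + e_ijk

    u_k   ~ N(0, sigma2_center)     (between-center)
    u_jk  ~ N(0, sigma2_subject)    (between-subject, nested in center)
    e_ijk ~ N(0, sigma2_within)     (within-subject / residual)

all mutually independent. Observations below the feature's LOD — defined as
the lowest detected intensity of that feature — contribute
P(y < log LOD) to the likelihood (a multilevel tobit model). The default
fixed-effect structure is intercept-only; the "adjusted" variant adds a
centered spline smooth in age plus linear BMI and sex, representing the ICC
relevant when an analysis is corrected for these confounders.

Estimands, all computed per posterior draw and then summarised by the
posterior median and equal-tailed 95% credible interval:

- **three-level ICC** `(sigma2_subject + sigma2_center) / total` — the
  correlation between two measurements of the same subject at the same
  center, treating between-center differences as biological signal;
- **within-center ICC** `sigma2_subject / total` — compares subjects only to
  subjects of the same center; draw-wise never exceeds the three-level ICC;
- **two-level ICC** `sigma2_subject / (sigma2_subject + sigma2_within)` from
  the model that ignores the center level;
- **data-scale ICC** `(exp(s2_b) - 1) / (exp(s2_b + s2_w) - 1)` — the
  Pearson correlation of replicate pairs on the original (exponentiated)
  scale implied by lognormality; defined here only for the two-level
  decomposition, and never larger than the log-scale ICC.

Computing the estimand per draw matters: the median of per-draw ICCs differs
from the ICC of median variances whenever the posterior is asymmetric or the
components are correlated (e.g. two draws (1,1,0) and (1,3,0) give median
ICC 0.625, not 2/3).

Repeatability classes follow the convention poor < 0.40 ≤ fair ≤ 0.75 <
excellent.

## Inference

Fitting is by blocked Gibbs sampling with data augmentation, written
directly against the model above (no general-purpose PPL):

1. each censored response is drawn from its truncated-normal full
   conditional (inverse-CDF sampling, numerically clipped for extreme
   tails);
2. regression coefficients from their joint normal conditional;
3. subject and center intercepts from independent normal conditionals,
   vectorised over groups;
4. variances from inverse-gamma conditionals.

Priors are weakly informative and data-scaled: half-Student-t(3, 0,
2.5·sd(y)) on each SD, implemented exactly via the inverse-gamma mixture
(sigma^2 | a ~ IG(nu/2, nu/a), a ~ IG(1/2, A^-2)), so every update stays
conjugate; Student-t(3, median(y), 2.5·sd(y)) on the intercept via a normal
scale mixture; flat priors on other coefficients. Covariates are
standardised internally and coefficients reported on the original scale.
`adapt_delta`-style step-size controls from HMC engines have no Gibbs
analogue and are not applicable here.

Defaults are 10 000 iterations × 4 chains with the first half discarded; the
built-in recovery and acceptance studies run at 2000 × 4 (and 1500 × 2 for
replicated bias studies), sizes at which the posterior-median ICC is stable
to well under 0.01 for ~300-sample designs. Chains start from dispersed
points; split R-hat and bulk ESS (via ArviZ) are reported per parameter,
with a pass flag requiring R-hat < 1.05 and ESS > 400 on the variance
parameters. Failing features are flagged, never dropped. Seeding is
hierarchical (master seed × feature substream × chain), so batch runs and
single-feature runs agree draw for draw.

The sampler was cross-validated during development against an independent
Gibbs engine (JAGS) with the identical model and priors; posterior medians
of all variance components agreed to within Monte-Carlo error.

### Degenerate inputs

All-censored features and designs with no replicated subject are rejected
(the within/between decomposition is unidentifiable). Constant data fit
without error but are flagged degenerate: variance posteriors collapse
toward the prior's lower range and the ICC is reported as undefined.

## Preprocessing rules

- **Blank filter:** a feature is removed when it is present in *every*
  blank sample and its median study-sample intensity is below 5× its median
  blank intensity (statistic and fold configurable; the representative
  statistic is a design choice — the rule's source convention names only
  "5-fold greater in intensity").
- **Detection filter:** keep features detected in ≥ 40% of samples, an
  inclusive comparison on the exact fraction.
- **LOD:** the minimum detected intensity per feature.
- **Annotation:** match features to a database of known-detectable
  compounds within ±10 ppm (computed against the database mass) and
  ±0.15 min, ranked by `|dppm|/ppm_tol + |dRT|/rt_tol`, up to 10 matches per
  feature. Isotope-pattern scoring is out of scope (no raw spectra).
- **Duplicate collapse:** when several features map to one compound, the
  feature with the highest posterior-median ICC is reported; ties break by
  narrower credible interval, then lexicographic feature id.

Filter order is blank filter, then detection filter; both stages are
idempotent and configurable.

## Synthetic data

The generator draws log-intensities exactly from the measurement model and
then exponentiates, so lognormality on the intensity scale holds by
construction. Censoring is applied per feature on the intensity scale at the
empirical quantile that hits a target detection rate; the threshold is
stored as the true LOD. Nondetects are emitted as missing cells (the
convention assumed throughout; zero-encoding of nondetects is not used).

The default design mirrors a four-center European serum study: centers of
48/25/43/41 subjects, 141 of 157 subjects sampled twice (298 samples), ages
50–70 (mean 60.5, SD 6.6), 61% female, BMI mean 25.3 (SD 4.1), repeat
samples ~107 days apart (dates are metadata only). Default per-feature
variance components are drawn independently as sigma2_within ~ U(0.3, 0.7),
sigma2_subject ~ U(0.2, 0.8), sigma2_center ~ U(0.02, 0.10): averaged over
features this puts the between-center share near 6% of the total and the
mean true ICC near 0.5, the regime typical of repeated-measures serum
metabolomics; detection-rate targets default to U(0.4, 1.0). All of this is
overridable per simulation.

What the generator does *not* emulate: chromatographic/spectral artifacts,
batch and injection-order drift, correlated censoring across co-eluting
features, heavy-tailed or skewed log-intensity errors, and correlation of
variance components across features. Passing recovery tests therefore
demonstrate correctness of the estimator under the model's own assumptions,
not robustness to their violation.

## Validation studies

- **Oracle equivalence:** in the uncensored limit, posterior medians of the
  within- and between-subject variances agree with a classical REML fit to
  within a few percent.
- **Recovery:** across a grid of true ICC {0.2, 0.5, 0.8} × detection
  {1.0, 0.8, 0.6} under the default design, the mean absolute error of the
  posterior-median ICC is ≈ 0.05–0.08 and pooled 95% CrI coverage ≈ 0.98.
- **Substitution bias:** at 40% censoring, the censored likelihood estimates
  the within-subject variance with smaller absolute error than LOD/2
  substitution in the large majority of replicates.
- **Null-covariate stability:** adding the age smooth, BMI and sex to
  covariate-free simulations leaves per-feature and median ICCs unchanged
  within MCMC error.
- **Back-transform:** the closed-form data-scale ICC matches the Pearson
  correlation of 10^6 simulated lognormal replicate pairs.

## Known limitations

- **Between-center variance at few centers.** With four centers the
  between-center variance has roughly three effective observations; its
  marginal posterior is strongly right-skewed under the weak half-t prior,
  and its posterior median sits well above the REML/method-of-moments point
  estimate (a factor ~2 in our checks, reproduced identically by an
  independent MCMC engine). Consequences: the three-level ICC is biased
  slightly upward at low true ICC (~+0.04 under the default design), the
  estimated between-center share overshoots small true shares, and ICC
  credible intervals are conservative (coverage near or above nominal).
  This is a property of Bayesian posterior summaries for weakly identified
  variances, not of the implementation; it diminishes as the number of
  centers grows and does not affect the two-level estimands.
- The adjusted-model ICC uses the estimand formula on the adjusted model's
  variance components (explained covariate variance is removed from the
  model, not subtracted from the denominator); with null covariates the two
  definitions coincide, consistent with the stability check above.
- Intercept mixing in the Gibbs sampler is slower than variance mixing
  (random-effect/intercept correlation); variance parameters, the quantities
  of interest, reach usable ESS at the default run lengths.
- Group summaries (chemical class, pathway) consume user-supplied mapping
  files; no ontology retrieval is performed.
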