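# Methods

This note records the statistical model, the generator design, the numerical
choices, and the limitations of the package.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The crossover model family and its estimation

All ten competing models are Gaussian linear models for an outcome y given a
susceptibility score G, an environment score E and optional covariates X.
G is min-max rescaled to [0, 1] inside every fit so that the "strong"
constraint (beta_E = 0) has a fixed meaning: the least-susceptible individual
observed is environment-insensitive.  E enters as-is, oriented so that larger
values are more adverse; consequently diathesis-stress anchors the crossover
at min(E) (the most favorable exposure observed) and vantage sensitivity at
max(E).  The crossover mean function is

    mu = beta0 + gamma'X + (beta_E + beta_S G)(E - c).

There is deliberately no free G main effect inside the six crossover models:
the lines for all susceptibility levels pass through the single point
(c, beta0 + gamma'X̄), which is exactly the substantive crossover claim.  A
free G offset would let the "crossover" drift off the data and destroy the
interpretation.  The four no-interaction alternatives (intercept, G, E,
G + E) guard against fitting ill-conditioned crossover models to additive
data.

Free-crossover (DS) models are estimated by the exact linear
reparameterization: weak DS on the basis {E, G·E, G}, strong DS on
{G·E, G}, with c = -coef(G)/coef(G·E), beta_S = coef(G·E) and, for the weak
model, beta_E = coef(E) and beta0 = intercept + beta_E·c.  Anchored and null
models are plain OLS in their basis.  Everything is closed form; there is no
iterative optimisation anywhere in the family.

The standard error of c uses the delta method through the ratio
-coef(G)/coef(G·E) with the OLS coefficient covariance (residual variance at
RSS/(n-p)).  A profile-likelihood interval (inverting
n·log RSS(c)/RSS(ĉ) against the chi-square(1) quantile) is available as a
cross-check mode; it guards against near-zero interaction coefficients,
where the delta interval degenerates.  If |coef(G·E)| falls below
1e-8 x sd(y) the crossover is flagged non-identified and the classification
can never select DS.

### AIC competition and classification

The likelihood is Gaussian with the residual variance at its MLE, so
loglik = -n/2 (log(2 pi RSS/n) + 1).  The parameter count includes the
intercept, every free slope, every covariate coefficient, the free crossover
(through the reparameterized G coefficient) and the residual variance —
identical accounting across all ten models, which is what makes the
competition fair.  Covariates enter every model identically for the same
reason.  Plain AIC is the default; AICc is a flag.

Numerically-zero residuals need care: on noise-free data several models fit
exactly and their log-likelihoods would be dominated by floating-point
residual noise.  The residual variance is therefore floored at
`1e-16 (var(y) + 1e-8 mean(y^2)) + 1e-300`, which makes all exact fits tie
exactly; ties (within 1e-9 of AIC) break to the fewest parameters, then to
the fixed model order.  A constant outcome thus classifies as
intercept-only, and noise-free additive data as G + E, by parsimony.

The winner maps to its label; a DS winner must additionally have an
identified crossover whose 95% interval lies inside [min(E), max(E)].  A DS
winner failing that check is reported as `ds_unconfirmed` rather than being
silently replaced by the second-best model — the DS verdict is defined by
the conjunction of both conditions, and a fallback would misstate the
evidence.

### Two-phase pipeline

Phase 1 screens every (score set, threshold, factor, outcome) cell with OLS
(`y ~ G + E + G:E + PCs`), reporting Est/SE/p per term and model R².
Benjamini-Hochberg adjustment is applied within families of cells sharing a
score set and outcome (all thresholds x factors jointly; with 4 thresholds
and 3 factors, m = 12).  The family rule is configuration, not dogma — the
appropriate family depends on the design.  Phase 2 applies the ten-model
competition to cells whose *raw* interaction p-value passes the gate
(default .05), with FDR-adjusted values reported alongside; covariates that
were non-significant in that cell's phase-1 model are trimmed first.
Missing data are the caller's responsibility (cells with missing values fail
loudly and are flagged; the run continues).

## The synthetic cohort

The generator emulates the statistical structure of a small
deeply-phenotyped young-adult cohort (n = 197 by default); it is the test
surface for every downstream stage and the source of the calibration
numbers.

**Genotypes.** Dosages come from a thresholded latent-Gaussian copula: per
block of `block_size` SNPs (default 5), two independent haplotype-like AR(1)
latent processes with first-order correlation `block_rho` (default 0.7) are
cut at the normal quantile of each SNP's allele frequency (uniform in
[0.05, 0.5] by default).  Marginals are exactly Binomial(2, maf); the
implied dosage correlation has a closed form through the bivariate normal
orthant mass, which the tests use as a moment oracle.  Blocks are
independent; positions are 10 kb apart so a block spans far less than a
1000 kb clumping window.

**Pseudo-GWAS.** A fraction `prop_causal` (default 0.3) of SNPs get true
effects ~ N(0, 0.15²); estimates add noise at the Wald standard error for a
declared pseudo sample size (default 20 000) and two-sided normal p-values.
Half the SNPs report the panel's other allele (sign-flipped) so the scorer's
allele reconciliation is always exercised.  This gives C+T realistic
behaviour — causal-enriched small p-values, LD-redundant hits — without any
external data.

**Adversity battery.** Thirteen subscale scores emulate a
questionnaire-plus-interview battery (5 CTQ-like, 5 ITEC-like, 3 CECA-like
named subscales), generated as linear images of four correlated latent
factors — intrafamilial adversity, deprivation, threat, sexual abuse — plus
uniqueness noise, mapped to a bounded 0-100 scale.  Defaults were calibrated
once: primary loadings 0.65 (0.85 for the two sexual-abuse indicators),
inter-factor correlations 0.45-0.50 (0.20 with sexual abuse), so that the
4-component oblique solution on an n = 197 battery explains about 63% of
total variance (SD across seeds ~1.4 points).  The sexual-abuse factor is
floored before mixing — `max(z - severity, 0)`, standardized, severity
1.0 SD — giving the heavy "no exposure" floor and strong right skew of a
sexual-abuse score in a non-clinical sample.  A lognormal transform was
considered and rejected: its *sample* skewness at n = 197 is too erratic for
a screen with a fixed cutoff, whereas the censored floor yields factor-score
skewness > 2 in every calibration seed while the other three factors stay
near-symmetric.

**Factor analysis.** Columns are standardized; principal components are
extracted from the correlation matrix; the top-k component loadings are
rotated obliquely.  Rotation is implemented in-package: direct oblimin
(gamma 0 = quartimin) via the gradient-projection algorithm, promax via
varimax + power-target Procrustes.  Variance explained is accounted
pre-rotation (top-k eigenvalue share), which rotation cannot change; the
tests assert this invariance rather than assuming it.  Factor scores use the
regression method, `Z R⁻¹ (Lambda Phi)`, with a pseudoinverse so noise-free
(rank-deficient) batteries remain scoreable.  The skewness screen masks any
factor with |sample skewness| > 2 (moment formula; cutoff configurable);
masked factors never enter the pipeline.

**Outcomes and reliability.** Outcomes are generated by the same mean
functions the fitting side uses (one shared definition), with the
susceptibility score being the cohort's own PRS at a chosen threshold,
min-max rescaled *before* generation so the generating and fitting G
coincide exactly — this is what makes sigma = 0 data refittable to machine
precision.  Measurement unreliability is emulated by adding noise with
variance (1-alpha)/alpha times the model variance, matching
Cronbach-alpha-style attenuation at the instrument reliabilities
(0.76-0.88).

**Targeting an interaction effect size.** `sigma_for_target_r2` solves for
the residual SD so that the regime's *unique* signal — the part of
beta_S·G·(E-c) orthogonal to {1, G, E}, i.e. the variance only an
interaction can explain — is a chosen share of the outcome variance.  For
anchored-crossover regimes this share has a structural ceiling: with c at
the environment boundary, most of the GxE term is collinear with the main
effects, and the attainable share (`max_attainable_r2`, roughly
alpha·v_int/v_mean) is typically 0.04-0.07 at these effect sizes, lower
still when G is a min-max-scaled PRS.  Requesting more raises an error by
default; the calibration studies pass `clip_to_attainable=True`, which
lowers the target to 95% of the ceiling for those replicates.  This is a
property of the model family, not a generator artefact.

## Calibration studies and their scales

`studies` re-runs the package's headline experiments; problem sizes are the
package's own choices, kept at the scale where a desk machine reproduces
them in minutes:

* **Classification accuracy** — 100 single-outcome cohorts per regime family
  at n = 197 through the full pipeline (genotypes → PRS → factors →
  outcome), weak/strong regimes alternating (null family cycles its four
  regimes), unique-signal share drawn uniformly in [0.03, 0.10] (clipped to
  the attainable ceiling where binding), reliabilities cycling the
  instrument alphas, DS crossovers at the 0.40 environment quantile.  A
  replicate is correct when the returned label's family matches the
  generating family.
* **Crossover coverage** — 500 weak-DS replicates at n = 197, checking the
  95% delta interval against the true crossover.
* **Null calibration** — 2000 null replicates for the exploratory screen's
  type-I rate; 500 fast all-null cohorts (12-cell families) for the
  probability that any FDR-adjusted interaction p clears .05.
* **Variance-explained** — 20 default batteries at n = 197.

What passing these shows — and does not.  The generator reproduces the
*statistical* structure the procedures consume: LD-blocked dosages,
noisy GWAS weights, correlated skewed adversity factors, attenuated
outcomes.  It does not reproduce real LD maps, item-level instrument
behaviour, non-Gaussian outcome floors, population stratification beyond
noise PCs, or selection effects in recruitment; accuracy measured here is
accuracy under the generative model, not a guarantee for any particular real
cohort.

## C+T details worth knowing

Clumping visits SNPs by ascending p (ties by SNP id, for determinism); the
index SNP claims same-chromosome neighbours within ±window with r² at or
above the cutoff.  LD can come from a dosage panel (squared Pearson
correlation, mean-imputed) or a long-format pair table (absent pairs count
as unlinked).  Threshold comparison is strict `<` (a flag switches to `<=`).
Allele reconciliation tries direct match, swap, then strand flip;
palindromic A/T / C/G pairs are dropped by default (policy: drop / keep /
strict), irreconcilable pairs always drop unless strict.  Missing dosages
are mean-imputed per SNP before scoring.  Scores are z-scored per threshold
by default so that model coefficients are comparable across thresholds;
standardization records (mean, SD) are kept.  SNP counts per threshold are
nested by construction.

## Known limitations

* The competition assumes a single G and a single E per test; latent
  multi-marker/multi-exposure composites are out of scope.
* The Gaussian likelihood is exact only for continuous, roughly homoscedastic
  outcomes; heavy-floored outcomes would need a different likelihood.
* The delta interval for c is symmetric and can be optimistic when the
  interaction coefficient is small relative to its SE; the profile interval
  is the recommended cross-check in that regime.
* Environment orientation is a convention (larger = more adverse); feeding a
  reversed scale swaps the diathesis-stress and vantage-sensitivity labels,
  by design.
* The `.raw` genotype dialect carries no positions; supply a marker sidecar
  to clump from `.raw` input.
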