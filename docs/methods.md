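# Methods

This note records the models implemented, the defaults and why, what the
synthetic generators do and do not emulate, and the numerical choices made
where the design was genuinely open.

## The signature model

The treatment-response signature is an elastic-net *logistic* regression
of the binary treatment label on standardized biomarkers — a probabilistic
classifier, which is what reporting a cross-validated AUC presupposes.
The objective is the glmnet form

    −(1/n)·loglik(b0, β) + λ[α‖β‖₁ + ((1−α)/2)‖β‖₂²],

intercept unpenalized, α fixed at 0.5.  It is solved by scikit-learn's
saga elastic net via the exact reparameterization C = 1/(nλ), so the KKT
conditions of the stated objective hold at the solution (tested via the
subgradient bound |∇_j| ≤ λα at zero coefficients).  λ = 0 is refused:
with p ≫ n the unpenalized fit is separable and unidentified.

*λ selection.* Leave-one-out cross-validation over a 50-point log-spaced
grid spanning four decades below λ_max = max_j |x_jᵀ(y−ȳ)|/(nα); the AUC
of held-out probabilities is the criterion and ties break toward the
larger (sparser) λ.  Folds whose training data lose an arm entirely are
skipped with a warning.

*Feature convention.* The trial measures each biomarker at baseline and
two post-treatment visits.  The default representation is the per-subject
mean of post-baseline visits on completers; `change` (post minus baseline)
and `wk12` are available, since which convention underlies published
signatures of this kind is typically unstated.

*Standardization.* Columns are centered/scaled with denominator n−1 on the
whole trial sample (arms pooled); the scaler is retained so new cohorts
can be placed on a scale.  Out-of-sample cohorts are standardized to
their own cohort-wide scale — the defensible default when the original
assay scale is not transferable.

*Permutation analysis.* Arm labels are shuffled (unstratified) and the
model refit B = 500 times at the observed λ; the empirical p per biomarker
is the proportion of permutations whose |coefficient| reaches the observed
one, hence a multiple of 1/B.  Refitting at the observed penalty (rather
than re-running λ selection inside every permutation) matches how the
analysis is done in practice and keeps the null distribution comparable to
the observed fit.  One subtlety matters for calibration checks: under
penalties strong enough to zero coefficients, the empirical p has an atom
at 1 (zero observed coefficient ties with every permutation), so the
uniformity of permutation p-values under the null is verified at a small,
ridge-dominated λ where coefficients are almost surely nonzero.

*Fold stability.* Selection counts and sign-consistency (relative to the
full-model sign) across the leave-one-out refits at the selected λ.

*Trial effect.* Clinical outcomes measured at all three visits are
analyzed with an identity-link GEE (exchangeable working correlation,
robust sandwich SEs); the treatment effect is the treatment × post-baseline
interaction.  Data with a single visit per subject fall back to OLS of the
outcome on treatment, to which the GEE reduces in that case.

## Instrument selection

Variant QC keeps a variant iff INFO ≥ 0.7, missingness ≤ 10%, MAF ≥ 0.01
and HWE exact p ≥ 1e-15, logging the first failing rule in that fixed
order.  The HWE test is the exact conditional test (sum of probabilities
of heterozygote tables no more probable than the observed one, given the
allele counts), computed in log space and symmetric in the homozygote
labels.

Phenotypes are inverse rank-normal transformed with the Blom offset,
z = Φ⁻¹((r−3/8)/(n+1/4)), average ranks for ties — the common GWAS
convention.  The association scan regresses the phenotype on each dosage
plus covariates: the linear family uses Frisch–Waugh residualization
(vectorized across variants, t reference on the residual df), the
logistic family a variant-batched Newton solver (Wald normal reference)
cross-checked against a conventional IRLS fit in the tests.  Missing
dosages are mean-imputed per variant so n is constant across variants.

Clumping is the standard greedy procedure: visit significant variants in
order of ascending p (position breaks ties); each accepted index discards
remaining variants within the window whose dosage r² exceeds the
threshold.  Defaults: p < 5×10⁻⁸, window 1 Mb, r² 0.01 for
exposure-side selection and 0.001 for disease-side (reverse-direction)
selection; all exposed as arguments.  cis filtering keeps variants within
±100 kb of the gene, bounds inclusive, coordinates 1-based.

## MR estimators

All two-sample estimators consume harmonized pairs: alleles aligned via
complements, outcome betas negated when allele order is swapped,
palindromic variants dropped when both EAFs fall in (0.42, 0.58) and
otherwise aligned by frequency.

- **Wald ratio** θ_j = Γ_j/γ_j with first-order delta SE |se_Γ/γ|
  (second-order optional).
- **IVW** is the zero-intercept WLS slope with weights 1/se_Γ²
  (equivalently Σw_jθ_j/Σw_j with w_j = γ_j²/se_Γj²).  Default is
  multiplicative random effects when J > 3: SE inflated by
  max(1, √(Q/(J−1))), normal reference — the convention of the widely
  used R implementations.  Cochran's Q is reported.
- **Weighted median**: ordered ratios, centred cumulative normalized
  weights, linear interpolation at 0.5; SE by parametric bootstrap
  (default 1000 draws) resampling (γ̂, Γ̂) from normals.
- **Weighted mode**: mode of the inverse-variance-weighted normal-kernel
  density of the ratios; bandwidth φ × 0.9·min(sd, 1.4826·MAD)·J^(−1/5)
  with φ = 1; argmax on a dense grid; bootstrap SE.
- **MR-Egger**: WLS of Γ on γ with free intercept after orienting γ ≥ 0;
  t reference with J−2 df and residual scale floored at 1.  The intercept
  and its p-value test directional pleiotropy.
- **MR-PRESSO**: observed RSS of leave-one-out-predicted weighted
  residuals versus its parametric null (default 1000 simulations);
  per-variant outlier p-values Bonferroni-corrected at α = 0.05; the
  corrected estimate is exactly IVW on the unflagged subset.  The
  distortion test is out of scope.

One-sample MR regresses the binary outcome on a standardized weighted
allele score (exposure-GWAS betas by default; unweighted optional) plus
covariates.  The bi-directional driver selects instruments separately per
direction (r² 0.01 forward, 0.001 reverse) and runs the suite both ways;
a direction with no instruments is skipped with a warning.

Observational associations are ML logistic / OLS fits with Wald CIs
throughout (comparability across methods); BH-FDR is applied within one
family per analysis type.  The mediator screen requires: direction
pairing consistent with a beneficial signature (raised-by-treatment ⇒
lower risk, lowered ⇒ higher risk), observational q < 0.05, and MR
*direction* agreement without an MR significance gate — imprecise but
concordant MR evidence supports candidacy, reversed significant pairings
are off-target signals.

## Synthetic data: what it emulates, and what it does not

*Trial generator* — 84 subjects, exactly 1:1 allocation, 94 biomarkers
with exchangeable correlation (default 0.1), three visits with
within-subject correlation 0.5, treatment effects added at post-baseline
visits only, 4 dropouts (2 per arm) whose follow-up visits are removed
(completers analysis).  Clinical outcomes carry default treatment effects
of −0.45 (total cholesterol), −0.59 (fasting glucose) and −0.39 SD
(LDL-cholesterol), the effect sizes such a trial is designed to detect.

*Genotypes* — two independent haplotypes per individual, each a latent
block-AR(ρ) Gaussian thresholded at the MAF quantile.  HWE holds by
construction; within-block dosage r² is tunable via ρ.  Not emulated:
realistic human LD maps, imputation error (INFO is a metadata field, set
to 1 by the generator), relatedness, population structure (covariates are
simulated stand-ins), X-chromosome conventions.

*Cohort* — phenotype = √h2 · z(genetic score) + c·U + noise with a single
shared standard-normal confounder U (loading c on exposure and outcome),
outcome ~ Bernoulli(logistic(α + θ·phenotype_z + pleiotropy + c·U)); α is
solved by root finding to |Δprevalence| < 1e-4.  Pleiotropic variants add
centred direct dosage effects; they default to a subset of the causal
variants (invalid instruments) but can be pinned to arbitrary indices,
e.g. to give the outcome its own genetic architecture for reverse-MR
studies.

*Two-sample pairs* — two independent cohorts under the same variant
truth; exposure file from a linear scan in cohort A, outcome file from a
logistic scan in cohort B (no sample overlap).  A summary-level generator
draws (γ̂, Γ̂) directly from the MR model with optional directional or
balanced pleiotropy, for estimator-level studies where cohort simulation
adds nothing.

Passing tests on these generators show the *procedures* are correct and
calibrated under the stated models; they do not certify behavior under
real-data pathologies (assortative mating, selection bias, batch effects,
fine-scale LD leakage into clumped instruments).

## Study designs used by the tests and acceptance script

Problem sizes are chosen so the full suite runs on one CPU in minutes
while each check retains clear resolution:

- *Parameter recovery*: 200 replicates of two 20,000-person cohorts, 50
  independent valid instruments, true θ = −0.16.  The architecture is
  strongly heritable and oligogenic (h² = 0.6, MAF 0.2–0.5, effect
  magnitudes alternating between 0.2–0.4 and 0.8–1.0 bands): MR-Egger is
  only consistent when the between-instrument spread of γ dominates its
  sampling error (the NOME/I²_GX condition, here I²_GX ≈ 0.98), so the
  recovery study is run where that assumption — like the valid-instrument
  assumptions of the other estimators — actually holds.  All 50 valid
  instruments are used directly, avoiding winner's-curse selection.
  The check is |mean − θ| ≤ 3 Monte-Carlo SEs per estimator.
- *Robustness*: 100 summary-level replicates, 10 instruments with 3–4
  carrying directional pleiotropy (mean 0.15); the weighted median must
  beat IVW in |bias| in ≥80%.
- *Calibration*: Egger intercept test at J = 25 under balanced pleiotropy
  (1000 replicates, rejection rate within 0.05 ± 0.02); GWAS-scan
  p-values on a permuted phenotype (2000 variants, n = 600) and
  permutation-test p-values on null trials (150 trials of n = 60, p = 8,
  B = 100, small fixed λ as explained above) must pass KS uniformity.
- *Outlier detection*: 12 instruments, one Γ shifted by 5 SE, 1000 PRESSO
  simulations; ≥90/100 flagged, with the clean-data global test rejecting
  ≤10/100.
- *End-to-end*: 100 seeds of the full pipeline (84-subject trial with 8
  planted ±1.0 SD responders of which 4 are mediators at |0.30| log-odds
  per SD; two cohorts of 20,000; 4 dedicated variants per heritable
  biomarker, h² = 0.3 each).  The signature's OR must be < 1
  observationally and in MR in ≥95 seeds and ≥80% of planted mediators
  recovered.  The pipeline fixes λ at 0.1·λ_max rather than running LOO
  inside every seed; the LOO path is exercised separately.

## Numerical choices and degenerate inputs

- saga tolerances: 1e-8 for reported fits (1e-12 where oracle agreement
  to 1e-4 is asserted), 1e-4–1e-6 inside cross-validation and permutation
  loops where only predictions or coefficient magnitudes matter.
- The batched logistic Newton adds 1e-10 ridge to the Hessian diagonal
  and caps iterations at 40; non-identified fits surface as large SEs
  rather than crashes.
- Monomorphic variants: ld_r2 returns NaN with a warning; constant
  biomarker columns are excluded from standardization with a warning;
  all-equal inputs to the INT raise.
- Empty clumping results and instrument-less MR directions warn and
  return empty/skipped rather than raising, so panel drivers can proceed.
- Bisection bounds for the prevalence intercept are ±30 on the logit
  scale; unattainable prevalences raise an ArithmeticError naming the
  target.
- Tie-breaks: clumping orders by (p, position); λ ties break toward the
  sparser model; weighted-median interpolation clamps to the extreme
  ratios when the crossing falls outside the grid.

## Known limitations

No GSMR/HEIDI, no MR-PRESSO distortion test, no Steiger filtering, no
correlated-instrument IVW, no multivariable MR, no survival outcomes, no
formal mediation proportion — the screen identifies direction-consistent
candidates only.  The LOO-CV AUC of a 94-biomarker model at n = 80 is
intrinsically noisy; the stability table and permutation analysis are the
intended complements, not substitutes, for external validation.
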