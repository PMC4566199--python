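# Methods

## Model

The unit of analysis is the hospital×payer combination.  For payer *j*
at hospital *i*, the payment-to-charge ratio `PCR_ij` (total payments ÷
total charges over the hospital's stays with that primary payer) is
modelled with a gamma GLM and log link,

    log E[PCR_ij] = α_j + β_j'·C_ij + γ_j'·H_ij + δ_j'·S_i ,

one equation per payer (Medicare, Medicaid, private, self-pay, other).
The gamma family matches a strictly positive, right-skewed ratio whose
variance grows with its mean; the log link keeps fitted PCRs positive
and makes coefficients interpretable as relative effects
(`exp(coef) − 1`).  Observations with `PCR ≤ 0` or `PCR > 1` are
excluded before fitting — they are outliers or unrepresentable under a
log link — and logged with the reason.

Covariate blocks, with the scaling used throughout:

- **Casemix** `C_ij` (hospital-level means over the group's stays):
  female share; age-band shares 0–17, 18–35, 36–45, 46–55 (reference
  56+); race shares Black, Hispanic, other/missing (reference White);
  in-hospital death share; APR-DRG severity shares for levels 2, 3, 4
  (levels 0 and 1 pooled as reference).
- **Hospital/market** `H_ij`: critical-access, rural-referral,
  sole-community and teaching flags; average DRG weight; Medicare wage
  index; HHI×10 and its square.  The HHI of hospital *i* is the sum of
  squared discharge shares over all hospitals within a 15-mile radius
  (configurable), shares measured by total discharges across payers.
  For the Medicare and Medicaid equations only: discharges/10,000 and
  its square, ALOS/10 and its square (ALOS = stay-weighted mean length
  of stay).
- **State** `S_i`: budget deficit per $1,000M (stored in $millions),
  per-capita income in $1,000s, nonelderly uninsured below poverty in
  100,000s, Medicaid eligibility thresholds for children and working
  parents as FPL ratios, Medicaid per-capita spending in dollars, CHIP
  enrollment rate, FQHCs per 1,000 nonelderly uninsured.  A state
  fixed-effects variant replaces this block with state dummies; it
  cannot predict for states outside the training sample and the
  prediction code says so explicitly.

## Estimation

**IRLS.**  For the gamma family with log link the working weights
`(dμ/dη)²/V(μ)` are identically 1, so each iteration is an OLS
regression of the working response `z = η + (y−μ)/μ` on the design.
Starting values come from OLS on `log y`; a deviance increase triggers
step-halving (up to 30 halvings); convergence is a relative deviance
change below 1e-8 (max 100 iterations, non-convergence returned with a
flag and a warning, never silently).  Linear predictors are clipped to
±30 to avoid overflow; rank deficiency is detected by pivoted QR and
reported with the offending column names.  Dispersion φ is estimated by
Pearson χ²/(n−p); the gamma shape used in the log-likelihood is 1/φ.
Inference is Wald with normal two-sided p-values and stars at p < .05 /
.01 / .001 (strict inequalities).  AICc counts the dispersion as a
parameter: k = p + 1, `AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`.

**Telser system.**  The five equations' errors are correlated within a
hospital, so after the individual (stage-1) fits each equation is refit
with the other four equations' stage-1 residuals appended as covariates
(stage 2, the default).  Residuals are response-scale `y − μ̂` by
default; Pearson and deviance variants are selectable and exercised in
tests.  Hospitals missing from some equations leave holes in the
residual table; the default `complete_case` policy restricts each
equation's stage-2 sample to hospitals with all four foreign residuals,
and `zero_impute` instead fills holes with 0 and logs the imputation.
Neither policy claims to reproduce any particular published sample
size; the choice is a documented open point.

**Iteration beyond stage 2.**  When more stages are requested, the
residuals carried forward are *structural*: `y − exp(X_sub β_sub)` with
the residual-term coefficients zeroed.  Raw stage-2 residuals already
have the cross-equation correlation absorbed, and feeding them forward
makes the procedure oscillate (measured: coefficient changes contracted
in only 4/20 replicates); with structural residuals the stage-to-stage
coefficient change norm contracts in 20/20 replicates.  Change norms
are computed over substantive coefficients only and reported so
convergence can be inspected; coefficient-norm growth beyond a bound
sets a divergence flag and warns.

**Prediction.**  New hospitals have no first-stage residuals, so
prediction from a stage-2 fit sets the residual covariates to their
null value 0 (stage-1 coefficients are available by flag).  A
consequence worth knowing: out-of-sample prediction RMSE from stage 2
is statistically indistinguishable from stage 1 in this generative
world (measured difference ≈0.05% of RMSE over 100 replicates) — the
second stage buys calibrated *inference* on the cross-equation
correlation, not better point prediction.

## Validation and comparison

Leave-one-state-out validation refits the system without one state and
scores its hospitals: per payer, in-sample RMSE, out-of-sample RMSE,
MAE, mean predicted and actual PCR, and the relative RMSE
(100 × out-of-sample RMSE ÷ the *all-state* mean actual PCR, which is
how the published relative errors are arithmetically consistent).

The CCR comparison pivots PCRs wide, keeps hospitals whose five PCRs
all lie strictly in (0, 1) — stricter than the per-equation filter,
where PCR = 1.0 is retained by default (both endpoints configurable) —
and computes pairwise Pearson correlations.  Significance uses the
t-transform of r with n−2 degrees of freedom; the source material
mentions chi-square tests for these correlations, which is nonstandard
and not reproducible as stated, so the conventional t-transform is used
and the discrepancy noted here.

## Synthetic world

The generator emulates the data-generating structure the analysis
assumes; it is a stated world, not a fit to any real dataset.

- **Geography.**  10 states × 114 hospitals by default (≈1,140
  hospitals, the scale of the study population).  Each state is a
  175-mile square with uniformly scattered hospitals, offset so markets
  never straddle states; 175 miles makes the expected 15-mile market
  hold 2–3 hospitals, putting mean HHI near 0.38.  Distances are planar
  Euclidean — no real geography is mimicked.
- **True PCRs.**  Per hospital×payer, covariates are drawn around the
  study population's means/sds (Beta/Dirichlet for shares with
  concentration 40, truncated normals and moment-matched lognormals
  elsewhere).  `η = α_j + slopes·x` with modest default slopes on six
  covariates and zeros elsewhere; the intercept is calibrated so the
  population mean of `exp(η)` equals the target mean PCR (.320, .367,
  .487, .456, .611 by payer).  The PCR is a gamma draw with shape ν = 8
  (CV ≈ 0.35, matching the observed cross-hospital spread once
  covariate variation is added) and mean `exp(η)`, coupled across
  payers by a Gaussian copula with correlation `R`.  Draws above 1.0
  are *flagged, not redrawn*, so the retention filter has real work.
- **Copula `R`.**  Major-payer entries follow the observed PCR-PCR
  correlation pattern (.77/.69/.62); self-pay/other entries are small,
  with the private↔self-pay entry set to −0.30 so that a CCR built from
  the three major payers is uncorrelated with self-pay in the
  population (the sign matches the observed pattern; the magnitude is a
  one-time calibration, frozen).
- **Stays.**  Counts per hospital-payer are lognormal around 4,190
  (Medicare), 2,050 (Medicaid), 3,000/600/500 (private/self-pay/other —
  the first two are the study population's means, the rest plausible
  fill-ins).  Charges are lognormal (median $25,000, log-sd 1);
  `payment = charge × true PCR × mean-one lognormal noise` (sd 0.2), so
  the aggregate ratio converges to the true PCR and equals it exactly
  at zero noise.  Categorical casemix attributes are allocated by
  largest-remainder quota from the hospital's true proportions, so
  realised shares equal the truth up to 1/n rounding; lengths of stay
  are gamma around the hospital's true ALOS; all within-stay noise
  scales have zero-noise configurations under which aggregation
  reproduces the truth exactly.
- **CCR.**  Equal-weight mean of the hospital's three major-payer true
  PCRs plus Gaussian noise (sd 0.07, one-time calibration), giving
  population correlations ≈0.75–0.79 with each major-payer PCR and ≈0
  with self-pay/other.
- **Reproducibility.**  One seed, fanned out to per-stage substreams
  (states/hospitals/truth/stays/CCRs), so any stage can be rerun
  independently; written datasets carry a manifest with config and file
  digests.

What the generator does *not* emulate: real claim-file layouts, ICD/DRG
codes (severity is just the 0–4 integer and the DRG weight a supplied
attribute), within-state spatial clustering, hospital entry/exit, or
any systematic payer-mix correlation with geography beyond what the
shared covariates induce.  A green test therefore certifies the
*estimators* — their calibration, bookkeeping and arithmetic — not the
realism of any particular coefficient value.

## Numerical and design choices

- Retention boundary: the regression filter keeps PCR = 1.0
  (`0 < PCR ≤ 1`); the correlation filter is strictly open.  Both are
  flags.
- CSV dialect: UTF-8, comma, RFC-4180 quoting, `%.17g` floats (binary64
  round-trip); exclusion logs are JSON lines.
- Default scale in tests and the acceptance script is reduced (tens of
  hospitals per state, ~100 stays per cell) purely for CPU budget; the
  generator's defaults remain the full-scale world.
- Simulation-calibration tolerances are 3-SE bands (binomial,
  Monte-Carlo, or Fisher-z as appropriate), never tuned to outcomes.

## Known limitations

- The stage-2 estimator is the sequential Telser approximation, not
  joint maximum likelihood over the five equations; no claim of full
  GLS efficiency is made, and with near-identical regressors across
  equations the second stage adds little beyond inference on the error
  correlations.
- Wald inference ignores the generated-regressor variance of the
  stage-2 residual covariates; the null-calibration test shows the
  practical size is if anything slightly conservative (~3–5% at
  nominal 5%).
- The eight state covariates require at least nine states in the
  training data to be identified alongside the intercept; smaller
  worlds must use the state fixed-effects variant or fewer state
  covariates.
- Dispersion is payer-equation-specific but homogeneous within an
  equation; no robust/sandwich covariance is provided.
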