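# Methods

## The statistical question

SLODR analyses commonly declare support when a fitted single-factor model
shows (1) negatively skewed latent ability scores and (2) residual
variances that grow with ability (a positive latent–residual-variance
correlation). Both quantities are computed from the same person × measure
table, and both are sensitive to a purely descriptive feature of that
table: the correlation between each person's mean score (WIM) and score
spread (WISD). This package implements the machinery to demonstrate and
quantify that dependence.

## Pipeline

1. **Preprocessing.** Scores are oriented so higher = better (negation for
   latencies, distance/time for running events), optionally trimmed at
   pooled percentiles, restricted to complete cases, and z-scored
   column-wise (sample SD, denominator n−1). Trimming happens before
   reversal and complete-case filtering. Percentile bounds pool all trimmed
   columns into one distribution by default (a per-column mode exists)
   and use linear-interpolation quantiles.
2. **WIM/WISD.** Per person, the mean and sample SD (denominator p−1)
   across the p standardized measures.
3. **Strategic slicing.** Persons are ordered by a slicing score —
   zWISD − zWIM (antidiagonal), zWIM + zWISD (diagonal), zWISD
   (horizontal) — and cut into k contiguous, equal-count groups (sizes
   differ by ≤1; remainder to the earliest groups; stable sort breaks ties
   by input order). WIM and WISD are z-scored before forming the score so
   both axes contribute comparably; a flag disables this. Conditioning a
   stripe on a narrow band of its score leaves within-stripe variation
   perpendicular to the score, which is what sets the within-stripe
   WIM–WISD correlation's sign: positive for antidiagonal, negative for
   diagonal, near zero for horizontal. Equal-count cuts (not equal-width
   bands) realize "approximately equal" subsample sizes exactly.
4. **Factor model.** Inside each stripe (and the full sample) the
   single-factor model Σ = ΛΛᵀ + diag(θ) is fit by minimizing the
   normal-theory discrepancy F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p with the
   factor variance fixed at 1, so loadings are in the standardized metric.
   Scores are standardized once globally; stripes are *not* re-standardized,
   so a stripe's covariance reflects its restricted range.
5. **Criteria.** Regression-method factor scores f̂ = ΛᵀΣ̂⁻¹x; per-person
   residual variance = mean squared deviation of observed scores from
   λⱼf̂ᵢ (divide by p); criterion 1 = significantly negative moment
   skewness of f̂ (D'Agostino z-test), criterion 2 = significantly positive
   Pearson correlation between f̂ and ln(residual variance), both at
   α = 0.05, no multiplicity correction. A Spearman variant of criterion 2
   is selectable.
6. **Aggregation.** The sweep enumerates every (direction, k) for
   k = 1..k_max and reports the size-weighted proportion of converged cells
   meeting both criteria, Σ n_c·I(both_c) / Σ n_c.

## Numerical choices

- **Optimizer.** L-BFGS-B on (Λ, ln θ) with an analytic gradient
  (dF/dΣ = Σ⁻¹(Σ−S)Σ⁻¹), a principal-component start and 3 jittered
  restarts; ftol 1e-14. θ is bounded below at 1e-4; a solution pinned
  there is a Heywood case and is reported as non-converged rather than
  hidden. When the optimum is no better than the zero-loading (diagonal)
  model the zero-loading solution is returned, so no-common-variance data
  yield ≈0 loadings instead of an arbitrary unidentified spike.
- **Sign convention.** Λ is flipped if Σλⱼ < 0 so higher latent score =
  better performance; latent skewness's sign depends on this, so it is
  enforced and tested.
- **χ² convention.** S uses denominator n and χ² = n·F, matching the
  defaults of the SEM software whose score estimator the regression method
  mirrors. The baseline for NFI/CFI is the independence model
  Σ_b = diag(S), df_b = p(p−1)/2; RMSEA = √(max(χ²−df,0)/(df·n)), reported
  as 0 for just-identified models (df = 0, e.g. p = 3).
- **Degenerate inputs.** Residual variances are floored at 1e-12 before the
  log (floor events logged); cells with n < p + 5 are skipped, not fitted;
  constant-WISD cells get an undefined (NaN) Spearman correlation and are
  excluded downstream; all skipped/failed cells appear in the output with a
  status, so attempted = converged + skipped + failed always holds.

## The synthetic generator

The generator emulates the structure the analysis assumes, not any
particular dataset: aᵢ ~ N(0,1); σᵢ = σ₀·exp(c·aᵢ); x_ij = λⱼaᵢ + σᵢε_ij;
then optionally a disturbance x_ij − dᵢb_ij with dᵢ ~ Exp(rate),
b_ij ~ U(0,1) (a minority of persons score well below their ability, which
skews scores negatively); then the monotone transform
y = (e^{βx} − 1)/β (identity at β = 0; β < 0 compresses the upper tail,
mimicking a ceiling); then optional hard censoring at pooled empirical
quantiles. The log-linear noise coupling guarantees a positive noise SD and
a monotone ability–variability relation of either sign — the simplest
mechanism that produces the WIM–WISD correlations the slicing analysis
manipulates.

Default study conditions used throughout tests and the acceptance script:
n = 2000 persons, p = 10 measures, λ = 0.7, σ₀ = 0.714 (unit marginal
variance when c = 0), coupling c = ±0.4 for the mechanism checks and c = 0
for the slicing sweeps, 20 seeds for sign-stability claims. Larger sizes
(n = 5000) are used where parameter-recovery precision is the point, and
200 replicates at p = 6 for the χ²-calibration check; these sizes are the
package's choices for stable Monte-Carlo checks.

What the generator does **not** emulate: multi-factor structure, serial
dependence across trials or years, site effects, panel attrition, or
realistic score discreteness. Passing tests therefore show that the
slicing artifact operates as described under a clean one-factor world; they
do not validate any substantive claim about real intelligence, RT,
athletic, or income data.

## Known limitations

- The factor model is deliberately single-factor; real datasets that
  motivated this design fit it poorly (that misfit is immaterial to the
  artifact being studied but matters for any substantive reuse).
- Quadratic (nonlinear) loadings — sometimes proposed as a third SLODR
  criterion — are out of scope; in practice models including them rarely
  converge on data of this kind.
- The choice of skewness significance test (D'Agostino) and of Pearson for
  criterion 2 are defensible defaults, not the only options; results near
  the significance boundary can shift under other choices, which is why
  both the estimator and the test are named in the outputs' documentation.
- Whether slicing cuts should be equal-count or equal-width along the
  slicing axis is a design choice; equal-count is implemented and should be
  reported alongside any results.
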