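# Methods

## The question and the estimators

A multivariate linear mixed model for K longitudinal measures stacks the
per-measure designs block-diagonally: `Y_i = X_i beta + Z_i b_i + e_i`,
`b_i ~ N(0, D)`, `e_i ~ N(0, Sigma_i)`, `V_i = Z_i D Z_i' + Sigma_i`.  The
"combined" working model uses the full `D` and `Sigma_i`; the "separated"
working model zeroes every cross-measure block, which is exactly the model
implied by fitting K univariate mixed models.

Both working models define *linear* estimators:

- fixed effects: `beta_hat_w = (sum_i X_i' W_wi X_i)^{-1} sum_i X_i' W_wi Y_i`
  with `W_wi = V_wi^{-1}`;
- random effects: `b_hat_wi = D_w Z_i' W_wi (Y_i - X_i beta_hat)` (the BLUP
  when the working model is true);
- predictions of `E(y_i | b_i)`: `y_hat_wi = X_i beta_hat + Z_i b_hat_wi`.

Because the estimators are linear, their error moments **under the true
joint model** are exact matrix expressions.  Writing `L = D_w Z' W_w` and
splitting the error of `b_hat` into its `b`-driven and `e`-driven parts,

```
b_hat - b = (L Z - I) b + L e            (beta known)
MSE matrix = (LZ - I) D (LZ - I)'  +  L Sigma L'
             \______ squared bias ____/   \_ variance _/
```

The "bias" term is the squared conditional bias given `b`, averaged over
`b ~ N(0, D)` — the convention under which the joint model's gain for
random effects is mostly a bias reduction (less over-shrinkage of sparse
measures).  With estimated coefficients the error picks up
`-L_i X_i (beta_hat - beta)`, with `beta_hat - beta = sum_j A_j (Z_j b_j + e_j)`;
the package accumulates the full covariance of this composite linear map,
including the cross-subject coupling through the shared `beta_hat`.  Fixed
effects are unconditionally unbiased under either working model, so their
MSE is pure variance, `trace(sum_i A_i V_i A_i')`.

MSE ratios (combined over separated) are formed from sums of selected
per-coordinate MSEs; because the combined working model *is* the evaluation
model, its predictor is MSE-optimal and every ratio is <= 1.  Subject
aggregation defaults to ratio-of-summed-MSEs; mean-of-per-subject-ratios is
available (`how="mean_of_ratios"`).

Two exact identities anchor the implementation: (i) if all cross-measure
covariances are zero, both working models coincide and every ratio is 1;
(ii) if `X_ik` is identical across measures *and subjects* and `Z_ik` is a
shared sub-matrix of `X_ik` with no missingness, the separated fixed-effects
estimator is fully efficient (the mixed-model analogue of the classical
seemingly-unrelated-regressions result).  The across-subjects part of (ii)
is essential: with heterogeneous subject designs the combined GLS weighs
subjects differently and the ratio drops below 1.

## Bivariate grid study

Two measures share an equally spaced time grid scaled to [-1, 1]; measure 1
is complete, a fraction `pmiss` of measure 2 is missing (completely at
random, or drop-out: only the first `n2 = round((1 - pmiss) n1)` visits
kept).  `D` (4 x 4) and `R` (2 x 2) are driven by four correlations: within
measure (`rho_k1 = rho_k2 = rho_k` by default), across measures for the
random effects (`rho_b`, applied to all four cross entries) and for the
residuals (`rho_r`).  Case A has unit variances; case B sets the measure-2
residual variance to 4; case C sets the measure-2 slope variance to 4.
Coefficients are treated as known, isolating the shrinkage comparison.

The default factorial grid is `rho_b, rho_r in {-0.9, -0.7, ..., 0.9}`,
`rho_k in {-0.5, 0, 0.5}`, `n1 in {6, 9, 15}`, `pmiss in {0, 1/3, 2/3}`,
both patterns; cells where `rho_b` and `rho_r` are large with opposite
signs (both magnitudes >= 0.5) are flagged "unlikely" (configurable rule)
and excluded from summaries.  Random-pattern cells average the bias and
variance matrices over 20 seeded pattern draws before the ratio is formed;
draw seeds derive from `(base_seed, n1, pmiss, draw)` only — never from the
correlations — so the sign-flip invariance `(rho_b, rho_r) ->
(-rho_b, -rho_r)` holds exactly cell by cell and designs are reused across
the correlation loop (full grid in ~15 s on one CPU).

Raw `D` matrices off the correlation grid can be indefinite; they are
projected to PSD by spectral clipping with diagonal renormalisation: clip
eigenvalues at a floor (default 0), reconstruct, rescale rows/columns so
the original diagonal is restored.  The repair is idempotent and leaves
already-PSD input untouched.  The precise variant of this classical recipe
is a package choice; results at repaired cells inherit it.

## Monte Carlo oracle

Every closed form is validated by simulation: draw `(b, e)` from the true
model, apply the working-model estimator (vectorised across replicates),
and compare.  The empirical squared bias uses a paired-noise design — one
`b` draw, two independent `e` draws; the cross-product of the two error
vectors is unbiased for the squared conditional bias.  The standard
validation set is 20 seeded random configurations spanning K in {1, 2, 5},
2-4 subjects, partial time-overlap between measures, random PSD covariance
structures; each form is checked at 100 000 replicates.  Verdicts use the
z of each form's MSE *pooled over the 20 configurations* (~10 pooled
checks): pooling has far more power against a systematic error in a closed
form, while per-run z-values are standard normal by construction and a
3-sigma cut across ~200 of them would fail by chance about 40% of the
time.  Per-run z-values are still reported.

## Synthetic five-marker cohort

The generator emulates a scleroderma-registry-like cohort on the
quantile-normalised scale: five Gaussian measures over up to 40 years since
onset, per-measure visit counts drawn negative-binomially to match the
registry-style targets (means 12.83, 12.40, 9.13, 7.47, 19.09; SDs 6.20,
6.01, 3.71, 3.28, 7.61 for pFVC, pDLCO, EF, RVSP, mRSS), floored at 4
observations per measure (the inclusion criterion).  Visit times are
uniform order statistics on a per-subject clinic-day process; the lung pair
and the cardiac pair are sampled on shared days and mRSS on clinic days, so
same-day cross-measure residual correlation is actually realised.

Random effects are intercept + slope per measure (10 x 10 covariance).  The
default `D` is a Kronecker structure — a 5 x 5 cross-measure correlation
(lungs 0.8; RVSP with lungs 0.6 and with mRSS 0.7; mRSS with lungs 0.5; EF
uncorrelated with everything) times a 2 x 2 within-measure correlation
(0.25) — scaled by SDs 0.7 (intercept) and 0.02/year (slope); residual
variance 0.3 with same-day correlations 0.3 (lungs) and 0.2 (cardiac).
These defaults were chosen once as plausible values on a quantile-normalised
scale (marginal variance near 1 over the follow-up window) and produce the
qualitative pattern of interest: the sparsest, strongly cross-correlated
measure (RVSP) gains most from joint modelling and the uncorrelated one
(EF) gains nothing.  Fixed effects use a natural cubic spline of time
(3 df, knots at pooled-time quantiles; built as first-column differences
of a 4-column cubic-regression-spline basis so its span excludes the
constant and `[1, NS, covariates, covariates x NS]` is identifiable),
with invented baseline-covariate distributions — their values are
irrelevant to efficiency ratios, which depend only on (X, Z, D, R).

What the generator does *not* emulate: informative (outcome-dependent)
visit processes, non-Gaussian marginals before normalisation, secular
changes in clinical practice, and drop-out by death.  Tests passing on
this cohort therefore demonstrate correctness of the machinery under
missingness-at-random with smooth trajectories, not robustness to those
features of real registries.

Transforms: `quantile_normalize` maps values through the empirical CDF with
ranks divided by (n + 1) (average ranks on ties) into standard-normal
quantiles; `orient_measures` multiplies RVSP and mRSS by -1 so that larger
is better for all five measures (an involution).

## Covariance estimation without a joint fit

Per-measure models are fitted by maximum likelihood with an ECM iteration
on per-subject sufficient statistics (`Z'Z, Z'X, Z'y, X'X, X'y, y'y`): the
coefficient step is GLS via the Woodbury identity, the E step the standard
random-effect posterior, with the observed-data log-likelihood evaluated in
closed form at every iterate (convergence at 1e-8 relative change, 500
iterations by default; non-convergence raises with the trace; a
near-singular `D` triggers a small eigenvalue floor with a warning).  The
whole m = 2000 five-measure fit takes a few seconds.

Cross-measure blocks are completed by moments: per-subject *unshrunken*
projections `b*_ik = (Z'Z)^{-1} Z'(y_ik - X_ik beta_hat_k)` satisfy
`Cov(b*_ik, b*_ik') = D_kk' + R_kk' P_k S P_k''` with `S` the shared-visit
incidence, so the empirical cross covariance minus the residual-driven
correction estimates `D_kk'` without shrinkage attenuation.  `R_kk'` is
estimated first, from sums of products of projection residuals at shared
visit times divided by their expected coefficient.  Subjects with fewer
observations than random effects for a measure are excluded from that
measure's pairs only.  The assembled 10 x 10 and 5 x 5 estimates are
PSD-repaired before use.  At m = 2000 the within-measure components are
recovered within 10% relative and cross correlations within 0.1 absolute,
and efficiency ratios evaluated at the estimates track those at the truth
within 0.05.

Yearly correlation diagnostics: the empirical table correlates subject-year
mean values (pairwise complete, cells with fewer than 3 shared subjects
left missing) for years 0-10; the implied table evaluates
`z_s' D_kk' z_t + [s = t] R_kk'` with `z_t = (1, t)`.  Pairwise-complete
correlations on sparse cells carry sampling SEs up to ~0.5, so quantitative
comparisons should restrict to well-populated cells (the test suite uses a
>= 100-subject overlap and compares means).

## Numerical choices and scale

- Tie tolerance for "same visit time": 1e-9 (times are exact doubles here).
- PSD tolerance for component validation: eigenvalues >= -1e-10; PSD-repair
  output guaranteed >= -1e-12.
- Marginal-covariance inverses are checked (`||WV - I||_max < 1e-8`);
  degenerate `V` raises.
- Problem sizes used by the shipped checks — full default grid (13 500
  cells, 20 pattern draws), 20 validation configurations at 1e5 replicates,
  one m = 2000 cohort — were chosen so the complete suite runs in a few
  minutes on a single CPU while keeping every tolerance at its stated
  sampling-theory scale.
- The acceptance script reports `t1` as 100 x (1 - lower quartile of the
  ratio), i.e. the % MSE reduction achieved at the 25th percentile of the
  case-B complete-data ratio distribution over likely cells, and `t2` as
  the minimum ratio over likely cells at 33% / 66% missingness (both
  patterns; random-pattern cells averaged over 20 seeded draws).

## Known limitations

- Residual coupling exists only at exactly shared times; serial correlation
  (e.g. AR(1)) and time-varying residual variance are out of scope.
- Efficiency is evaluated at *given* covariance components; uncertainty in
  estimated components is not propagated into the ratios.
- The mean structure is assumed correctly specified for both working
  models; misspecified-mean efficiency is not addressed.
- Non-Gaussian outcomes and non-ignorable missingness are not modelled.
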