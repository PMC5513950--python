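# Methods

## Observation model

A batch methanogenic assay yields cumulative methane readings
`m_{r,i}` (mmol per litre of liquid) from replicate vial `r` at time
`t_i` (hours). The kinetic mean is the modified Gompertz curve

    M(t) = P · exp(−exp((Rm·e/P)·(λ − t) + 1)),

a three-parameter sigmoid in which `P` (mmol/L) is the production
potential, `Rm` (mmol L⁻¹ h⁻¹) the maximum rate — analytically the slope at
the inflection `t = λ + P/(Rm·e)`, where `M = P/e` — and `λ` (h) the lag
time. Observations are modelled as `m = M(t) + ε` with iid Gaussian
`ε ~ N(0, σ²)`. Duplicate vials of one condition are pooled into a single
likelihood with one parameter set: the tabulated outputs are per condition,
the duplicate design exists to average vial-to-vial noise, and a two-vial
design cannot support replicate-level random effects.

The error model and the treatment of `σ` are the package's own choices; no
heteroscedastic or weighted variants are offered.

All inference is parameterised by natural logarithms
`(ln P, ln Rm, ln λ, ln σ)`. This enforces positivity structurally and
makes the box prior (below) a log-uniform prior on the natural scale. A
consequence is that `λ = 0` is not representable: "no lag" appears as a
posterior concentrated below the time-grid resolution and should be read as
"< resolution".

### Numerical safeguards

The inner exponent `(Rm·e/P)(λ − t) + 1` is clipped to [−700, 700] before
exponentiation. The lower clip keeps the curve computable arbitrarily far
past the plateau (the induced error is below 1e-300); the upper clip only
suppresses a spurious overflow warning on curves that evaluate to exactly 0
in double precision anyway. Deep in the lag phase `M(t)` underflows to 0
and near the plateau it rounds to `P`; strict monotonicity and the open
bounds `0 < M < P` hold exactly wherever the value is representable, and
the test suite asserts them on that interior.

## Prior

The prior is uniform on a box in log space, with data-derived bounds wide
enough to contain any plausible estimate:

| coordinate | lower | upper |
|---|---|---|
| ln P | ln(0.5 · max observed M) | ln(10 · max observed M) |
| ln Rm | ln(0.01 · s̄) | ln(100 · s̄) |
| ln λ | ln(10⁻³ h) | ln(t_max) |
| ln σ | ln(10⁻³ mmol/L) | ln(max observed M) |

where `s̄` is the largest per-replicate finite-difference slope of the
observed series and `t_max` the last sampling time. The factors are
configurable (`PriorFactors`) and the realised bounds are written to run
metadata. A series with no positive slope or all-zero methane is rejected
as degenerate rather than fitted.

## Maximum likelihood: hybrid global + local search

Stage 1 is differential evolution (scipy) over the three kinetic log
coordinates within the prior box: an initial population of 200 individuals
drawn uniformly in the box, at most 1000 generations, and early stopping
once the best objective has improved by less than 1e-8 for 50 consecutive
generations. The objective is the σ-profiled negative log-likelihood: for
a Gaussian likelihood the conditional MLE of σ is the residual RMS, which
is substituted analytically (clipped to the σ prior bounds — the profiled
objective remains a monotone function of the residual sum of squares under
clipping, so the minimiser is unaffected). Mutation (0.5, 1.0) and
recombination 0.7 are library defaults, recorded here; only the population
size and generation cap are protocol-fixed.

Stage 2 refines the stage-1 optimum with bounded trust-region-reflective
least squares on the kinetic log parameters (tolerances 1e-10), then sets
`σ̂` to its exact joint-MLE value. Because profiling is exact for this
likelihood, the result is the joint optimum over all four coordinates; a
gradient-free comparison guarantees the refinement never reports a worse
log-likelihood than stage 1 (if the local stage fails, the stage-1 result
is returned with `converged = False`). Both stages are deterministic given
the seed.

## Posterior sampling

Adaptive random-walk Metropolis on the full 4-dimensional log vector.
Design choices:

* **σ as a fourth sampled coordinate.** Extending the three-component
  kinetic vector with `ln σ` (log-uniform) propagates noise uncertainty
  into the curve bands; downstream stages consume only the (P, Rm, λ)
  marginals.
* **Proposal.** Joint multivariate Gaussian. The covariance is initialised
  from the Laplace approximation at the MLE (inverse finite-difference
  Hessian of the negative log-posterior, eigenvalue-floored to positive
  definite) scaled by 2.38²/d, and re-estimated every 100 burn-in
  iterations from the chain history; a Robbins–Monro recursion on a global
  log step (gain (i+1)^−0.6) targets an acceptance rate of 0.3. All
  adaptation stops at the end of burn-in, so the retained draws come from a
  fixed-kernel Markov chain.
* **Initialisation.** Each chain starts at the MLE plus Gaussian jitter of
  0.05 per log coordinate, capped at 3 Laplace posterior standard
  deviations per coordinate. The cap matters for near-noiseless data,
  whose posterior is orders of magnitude narrower than a fixed 0.05
  jitter; without it a chain starts astronomically far (in posterior mass)
  from the mode and the acceptance rate collapses.
* **Bookkeeping.** Default: 3 chains × 20000 iterations, 2000 burn-in,
  thinning 10 → exactly 1800 retained draws per chain, 5400 pooled. The
  reduced configuration used by the calibration experiments is 1 chain ×
  5000 iterations, 500 burn-in, thinning 5 → 900 draws.
* **Diagnostics.** The potential scale reduction factor is computed as
  √(1 + B̄/W) with `B̄` the variance of per-chain means and `W` the mean
  within-chain variance. This variant equals exactly 1 for identical
  chains and ~1 + 1/(2n) for independent well-mixed chains; the classic
  estimator's (n−1)/n correction would report values below 1 in the
  identical-chain limit. Values above 1.05 raise a warning, as do
  post-burn-in acceptance rates outside [1%, 90%]. The statistic agrees
  with arviz's rank-normalised R̂ to 0.02 on well-mixed runs (tested).

## Reporting

The 95% confidence region of a condition is rendered as a pointwise curve
band: 300 draws subsampled without replacement (seeded) from the pooled
retained draws, each evaluated on the time grid, summarised by pointwise
empirical 2.5/50/97.5% quantiles with linear interpolation. Time-point
summaries at t₂₀/t₆₀/t₁₂₀ use *all* retained draws; the "95% deviation" is
half the central-interval width, the pointwise-quantile reading of a
shaded confidence band. Whether such tabulated deviations should instead
be projections of a joint parameter region is genuinely open; pointwise
quantiles are what a plotted band depicts, so that is the implemented
meaning. Comparisons report `100·(M_b − M_a)/M_a` from the central
estimates and flag whether the two 95% intervals overlap; a difference is
called supported only when they are disjoint, a deliberately conservative
reading of visually non-overlapping confidence curves.

## Synthetic data and calibration

The generator mirrors the assay design: duplicate vials, 12 sampling times
evenly spaced over 4–150 h (a ~6-day incubation), additive Gaussian noise
truncated at zero (methane cannot be negative; at the default noise level
the truncation bias is negligible because the curve is ≥ several σ above
zero at every scheduled time). Default truths: hydrogenotrophic
P=30 mmol/L, Rm=0.6 mmol L⁻¹ h⁻¹, λ=5 h; aceticlastic P=18, Rm=0.25, λ=10 —
plausible magnitudes consistent with the 20 mM-substrate stoichiometric
ceilings (an aceticlastic truth may not exceed 20 mmol/L, the 1:1 yield of
20 mM acetate). Noise defaults to σ = 2% of P. These are synthetic
stand-ins, not measured values.

Two calibration experiments define what "working" means here:

* **Coverage**: simulate N datasets, run the full pipeline on each
  (reduced MCMC configuration to fit desk scale), and count how often the
  central 95% credible interval contains the truth, per parameter.
  Correct-specification coverage at N=200 lands within ±3 percentage
  points of nominal (2× binomial SE); at the 50% level it lands near 50%.
  Datasets whose fit or sampler raises a convergence warning are excluded
  and counted.
* **Recovery**: relative bias and RMSE of posterior medians. Noiseless
  data reproduces the truth to ~1e-6 relative; at σ = 2% of P with 15 time
  points the relative RMSE of the P median is below 5%.

What passing these experiments does *not* show: real assays have
non-Gaussian and possibly autocorrelated measurement error, vial-to-vial
kinetic heterogeneity that pooling hides, headspace-to-liquid conversion
effects, and occasional non-sigmoid curves (diauxie, inhibition onset
mid-assay) that the single Gompertz mean cannot represent. Calibration
here certifies the inference machinery under the stated model, not the
model itself. Known limitations besides these: no alternative kinetic
models (first-order, logistic, Richards), no formal hypothesis tests, and
no mechanistic dose-response model for metal effects — treatments enter
only as separate conditions with their own parameter sets.
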