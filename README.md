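# methanofit

Bayesian kinetic analysis of batch methanogenic activity assays.

Anaerobic sludges and enrichment cultures are routinely characterised by
sealed-vial batch tests: duplicate vials are fed H₂/CO₂ or acetate, headspace
methane is measured by gas chromatography over a ~6-day incubation, and the
resulting cumulative curves are compared between treatments (for example
increasing doses of nickel or cobalt) and controls. `methanofit` turns those
long-format time series into kinetic parameter estimates with honest
uncertainty, 95% credible curve bands, and time-point comparisons.

## Model

Cumulative methane follows the modified Gompertz curve

```
M(t) = P · exp( −exp( (Rm·e/P)·(λ − t) + 1 ) )
```

with `P` the methane production potential (plateau, mmol/L), `Rm` the maximum
production rate (mmol L⁻¹ h⁻¹, the slope at the inflection point
`t = λ + P/(Rm·e)`), and `λ` the lag time (h). Observations are modelled as
the curve plus iid Gaussian noise of scale `σ`, with a condition's duplicate
vials pooled into one likelihood.

Inference proceeds in log-parameter space:

1. **Hybrid MLE** — a population-based evolutionary global search
   (population 200, ≤1000 generations) over a data-derived log-uniform prior
   box, refined by bounded gradient-based least squares.
2. **MCMC** — adaptive random-walk Metropolis on
   (ln P, ln Rm, ln λ, ln σ) under the log-uniform prior; by default three
   chains of 2×10⁴ iterations, 2×10³ burn-in, thinning 10 (1800 retained
   draws per chain), with a Gelman–Rubin-style scale-reduction diagnostic.
3. **Reporting** — 95% confidence-region curve bands drawn from 300 posterior
   curves, summaries of M(t) ± 95% deviation at t₂₀/t₆₀/t₁₂₀ h, and
   treatment-vs-control percent changes (a difference is called supported
   only when the 95% intervals are disjoint).

A synthetic-assay generator with known truth drives coverage and
parameter-recovery calibration experiments.

## Worked example

```sh
methanofit simulate --seed 11 --out assay.csv --truth-out truth.yaml
methanofit fit --input assay.csv --condition Control --seed 3
```

prints the hybrid maximum-likelihood estimate (the simulated truth is
P=30 mmol/L, Rm=0.6 mmol L⁻¹ h⁻¹, λ=5 h with σ=0.6 mmol/L noise):

```
condition=Control P=29.9162 Rm=0.5938 lambda=4.2619 sigma=0.4729 loglik=-16.0841
```

Then sample the posterior and summarise:

```sh
methanofit mcmc --input assay.csv --condition Control --seed 5 --draws-out draws.csv
methanofit report --draws draws.csv --condition Control --seed 6 \
    --band-out band.csv --summary-out summary.csv
```

`summary.csv` holds one row per condition, value ± 95% deviation per time
point:

```
condition,M20_mmol_per_l,dev95_t20,M60_mmol_per_l,dev95_t60,M120_mmol_per_l,dev95_t120
Control,9.3928,0.5368,26.1327,0.3535,29.7653,0.3140
```

i.e. by 20 h the culture has produced ≈9.4 mmol/L methane, by 60 h ≈26.1,
and by 120 h it sits at its ≈30 mmol/L plateau, each with a ±95% credible
half-width. `methanofit compare --summary ... --control Control
--treatment Ni-H-8 --time 120` then reports the percent change at the
plateau and whether the two intervals overlap.

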