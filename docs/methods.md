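# Methods

## Scope and model

`mixtox` analyses fixed-endpoint mortality bioassays of two agents (A, B)
and their binary mixtures, and scores mixture interaction with the
co-toxicity coefficient (CTC).  Time-to-death modelling, >2-component
mixtures, and alternative interaction frameworks (Bliss independence,
Chou–Talalay) are out of scope; the CTC's additive reference is the
weighted harmonic mean of the component LC50s, which coincides with Loewe
dose additivity for a fixed-ratio mixture.

### Abbott correction

Observed treatment mortality is corrected for background mortality as
`(p_t − p_c)/(1 − p_c)`, the standard form of Abbott's correction, with
the result clamped to [0, 1].  Clamping can only occur when treatment
mortality falls below control mortality — sampling noise under the model
— and emits a warning.  Control batches are identified by `dose == 0`
*and* the `is_control` flag; a disagreement between the two is an input
error rather than a silent choice.  Mortality is a fraction in [0, 1]
everywhere inside the library; percentages exist only at I/O boundaries.

### Dose-response models

Both models regress on `log10(concentration in declared units)`.  Dose
gradients are often recorded as dilution exponents of an unreported stock;
that coding is stock-dependent and irreproducible, so every fit records
the convention `log10_concentration` in its serialized summary.

* **Linear** (`fit_linear_logdose`): OLS of corrected mortality (percent)
  on log10 dose, the classic "virulence equation".  Fast, closed-form,
  and adequate when the dose window brackets the LC50 symmetrically; the
  acceptance script quantifies its bias on an asymmetric gradient.
  Predictions are clamped to [0, 1] only at evaluation, never during
  fitting.  A constant response gives a zero-slope fit with a warning
  (its LC50 is then undefined and `estimate_lc` raises).
* **Probit** (`fit_probit`): binomial GLM with probit link via
  statsmodels, weighting Abbott-corrected per-dose proportions by the
  pooled number exposed.  0%/100% observations are handled by the
  likelihood without continuity correction; complete separation (no dose
  with intermediate mortality) aborts with guidance, since the slope is
  then unidentified.

Goodness of fit is a binomial Pearson chi-square of observed vs expected
dead counts; adjacent doses are merged until each cell expects at least
one death and one survival, so near-empty cells cannot dominate the
statistic.  For the probit model r² is reported as the squared
correlation of observed and fitted proportions (no canonical r² exists
for a GLM); for a two-dose probit fit the model is saturated and the
chi-square is zero by construction.

`estimate_lc` inverts the fitted line: `10^((100p − intercept)/slope)`
for the linear model and `10^((Φ⁻¹(p) − intercept)/slope)` for probit.

### CTC and classification

With A as the index-100 reference: `TI_B = LC50_A/LC50_B × 100`,
`ATI = LC50_A/LC50_M × 100`, `TTI = 100·w_A + TI_B·w_B`,
`CTC = ATI/TTI × 100`.  Property tests verify the algebraic identities:
CTC = 100 exactly at the harmonic-mean additive LC50, equivalence with
the closed form `100·LC50_additive/LC50_M`, invariance under swapping the
reference agent and under rescaling all LC50s, and strict inverse
proportionality in LC50_M.

Classification uses the conventional thresholds with the cumulative band
closed: synergism strictly above 120, antagonism strictly below 80,
cumulative on [80, 120] inclusive — "between 80 and 120" is read as
inclusive, "higher than 120"/"less than 80" as strict.

All three LC50s entering a CTC must carry the same declared unit; mixing
mg/L with conidia/mL is a hard `UnitMismatchError`.  When one agent is
dosed in spore counts, the caller must first convert to a common potency
unit — the library deliberately refuses to guess a conversion.  Ratio
parts like 9:1 are interpreted as weight fractions of the formulated
agents, normalized to sum to 1.

## Bootstrap uncertainty

CIs are percentile bootstrap intervals, stratified by dose, deterministic
for a fixed seed (NumPy `SeedSequence`; the three assays of a CTC get
independent spawned streams).  Two resampling units are offered:

* `insect` (default): within each dose, individual insects are resampled
  from the pooled group — equivalent to a binomial draw at the pooled
  observed proportion.  With ~90 insects per dose the variance estimate
  is nearly unbiased; measured coverage of the nominal 95% CTC interval
  at the standard design is ≈ 0.94.
* `replicate`: whole replicates are resampled within dose.  With only 3
  replicates per dose this understates sampling variance by roughly
  (R−1)/R and measured coverage drops to ≈ 0.85, so it is not the
  default; it remains available for designs with many replicates or
  with overdispersion between replicates (which the binomial scheme
  would miss).

More than 50% failed bootstrap fits (non-positive slope) raises an error
instead of a silently unstable interval.  The linear model is used inside
the bootstrap; it is closed-form and fully vectorized across replicates.

## Synthetic data generator

`simulate_bioassay` draws dead counts `Binomial(n, p)` with
`p = c + (1−c)·Φ(slope·(log10 d − log10 LC50))` — a probit sigmoid with
background mortality `c`.  The generative truth model is deliberately
probit while the default analysis is the simpler linear fit, so recovery
tests measure the estimator actually used in practice on realistically
curved data.

Defaults mirror the standard whitefly-nymph assay: 5 dose levels spaced
10-fold, 3 replicates × 30 insects per dose, zero control mortality,
probit slope 1.5 per log10 dose (typical insecticide steepness), true
LC50s of 5 and 20 mg/L (the same order as real single-agent potencies in
this system).  Dose series default to being centered on each treatment's
true LC50, emulating an experimenter bracketing the expected potency;
explicit series can be supplied to study mis-centered designs.  The
mixture's latent LC50 derives from the target CTC by the closed form
`LC50_M = LC50_additive × 100/CTC`.

Per-experiment seeds come from `SeedSequence([master_seed, index])`, so
repeated experiments are mutually independent yet the whole study is a
pure function of the master seed.

What the generator does *not* emulate: between-replicate overdispersion,
time-varying mortality, dose-measurement error, and any non-probit shape
of the true curve.  Passing recovery tests therefore show the estimator
chain is correct and well-calibrated under binomial sampling at the
stated design — not that real assays are free of those extra error
sources.

## Problem sizes and measured behaviour

The validation suite uses 500 simulated experiments per true CTC
∈ {50, 100, 200} with 400 bootstrap replicates each (the bootstrap is
vectorized, so this takes seconds), 200 repeated experiments for CI
coverage of the single-agent LC50, and 10,000 random draws for the
algebraic identities.  At the standard design the median estimated CTC
falls within a few percent of truth and 95% CI coverage lands near 0.94.
On a noise-free assay (expected counts) the estimated CTC is within 2% of
truth — the residual being the discretization of the 5-dose design.

The acceptance script also contrasts the two fitters on the study's own
asymmetric azadirachtin gradient (0.5–500 mg/L around a true LC50 of
5.76 mg/L): the probit median recovers the truth almost exactly while the
linear fit is biased upward by ~45%, a known weakness of the linear
approximation when the dose window is not centered on the LC50.

## Known limitations

* Published mixture tables rarely report the x-variable coding, stock
  concentrations, or the standalone LC50 of the second agent, so external
  numeric cross-checks of CTC values are generally impossible; validation
  here is algebraic and simulation-based.
* The linear fitter's LC50 is biased on asymmetric dose windows (see
  above); prefer the probit model when the gradient is off-center.
* The insect-level bootstrap assumes within-dose binomial sampling;
  strong between-replicate heterogeneity would call for the replicate
  scheme and more replicates.
* Compatibility metrics are descriptive summaries; no EC50 of the
  fungicidal effect is fitted.  Whether the 0.5 cm inoculation plug is
  subtracted from colony diameters is a config flag (default off), as
  published protocols often leave this unstated.
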