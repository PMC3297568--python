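# Methods

## Model

`sepsim` implements a coarse-grained compartmental ODE model of the acute
inflammatory response to cecal ligation and puncture (CLP) sepsis in the
rat, centered on neutrophil trafficking between blood, peritoneum and
lung. The system integrates 19 states:

| block | states |
|---|---|
| infection | bacteria `B` (CFU/ml, peritoneum) |
| neutrophils | marrow reserve `N_bm`; blood resting/primed/activated `N_r`, `N_p`, `N_a`; peritoneal `N_t`; lung-sequestered `N_s`; lung `N_l` (cells/ml) |
| effectors | pro-inflammation `PI`, anti-inflammation `AI`, damage `D` (unit interval) |
| observables | `O_TNF`, `O_IL1b`, `O_IL6`, `O_IL10`, `O_Lsel`, `O_HMGB1`, `O_CRT`, `O_ALT` (normalized unit scale) |

Interactions are written as Hill-gated (HillCube-style) kinetics with a
global Hill exponent of 3. Concentration-valued regulators use the plain
Hill gate `x^3/(x^3+K^3)`; unit-interval regulators use the normalized
variant rescaled to equal 1 at a fully-on regulator, which keeps `PI`,
`AI`, `D` and the observables closed in [0, 1] under relaxation dynamics
`dx/dt = (gate - x)/tau`.

Balance terms, per block:

* **Bacteria.** A CLP source `k33 * g` (severity grade `g` in [0, 1]) and
  logistic growth, both gated by `(1 - B/B_inf)` so the carrying capacity
  `B_inf = 1e9` CFU/ml is an exact plateau; killing by tissue neutrophils
  `k34 * N_t * f(B)` with `f(B) = min(B, f_sat)` capturing the saturation
  of per-cell killing capacity at high burden (`f_sat = 1e8` CFU/ml);
  removal by resident macrophages `0.1 * min(B, B_mac)` with
  `B_mac = 1e5` CFU/ml.
* **Neutrophils.** The marrow reserve releases cells at a basal rate
  `k8 = 3.22e-6 /hr` plus a bacteria-gated surge bounded by
  `k10 = 3.15e-7 /hr`; constant granulopoiesis equal to the basal
  homeostatic release keeps the pre-CLP state an exact fixed point while
  letting the reserve deplete during the surge. Resting cells are primed
  by the local infection (threshold on `B`), primed cells migrate to the
  peritoneum at a bacteria-gated rate with a basal leak, and both resting
  and primed cells are systemically activated by `PI`. Activation is the
  pathological branch: activated cells cannot migrate to tissue, are
  sequestered in lung capillaries (PI-gated), and sequestered cells
  transmigrate into lung tissue (PI-gated, sharing the sequestration time
  constant). Migration to the peritoneum is additionally impaired by a
  `(1 - gate(PI))` factor — the model's representation of
  activation-induced loss of chemotactic competence — and limited by the
  tissue capacity `2e7` cells/ml. Blood-to-tissue and blood-to-lung
  fluxes are scaled by the volume ratios 34.4/25 and 34.4/48.
* **Effectors.** `PI` is activated by bacteria or damage (OR-combined
  gates) and inhibited by `AI`; the inhibition is partial, moderated by a
  factor `(1 - PI)` so anti-inflammation cannot fully counteract a
  saturated inflammatory state. `AI` is activated by `PI` or `D`; `D` by
  sequestered or lung neutrophils. All three relax with their own time
  constants.
* **Observables.** No direct cytokine-cytokine interactions are modeled.
  Each observable relaxes toward a sigmoid of its driver: TNFa, IL-1b and
  IL-6 follow `PI`; IL-10 follows `AI`; HMGB1, creatinine and ALT follow
  `D`; L-selectin follows the neutrophil activation flux (the sum of the
  three PI-gated transitions resting->activated, primed->activated,
  activated->sequestered) normalized by a reference flux of 1e6
  cells/ml/hr.

During hemoadsorption (default window 18-22 h post-CLP) Hill-type
elimination terms are subtracted from the `N_a`, `PI` and `AI` balances;
outside the window they are exactly zero, and the integrator is restarted
at both window edges so the discontinuity never straddles a step.

**Survival rule.** A virtual animal survives iff at the 200 h horizon
`B < B_crit` and `PI < 0.5`. `B_crit` defaults to `3e7` CFU/ml, between
the model's resolving (~1e7) and fulminant (~1e9) end states; it is a
configuration value, not a constant of the model.

## Parameters

The 57-entry registry (see `sepsim.registry`) holds 34 dynamic
parameters sampled by MCMC, 16 observation-mapping parameters (one
threshold/time-constant pair per observable, fitted once jointly over
both cohorts and frozen), and 7 physical constants. The structural
anchors of the model — the physical constants, the rates
`k8 = 3.22e-6 /hr`, `k10 = 3.15e-7 /hr`, `k33 = 9.4e7 /ml/hr` and
`k34 = 6.61e-8 ml/cell/hr`, the global Hill exponent, the CLP
measurement protocol and the survival thresholds — are fixed by the
study design the package models; the remaining baseline values are
calibration choices, fixed once so that:

* with `g = 0` the homeostatic state is exactly stationary;
* with the default severity `g = 0.08` the baseline (survivor)
  parameterization clears the infection (`B(200h) ~ 1e7`, `PI < 0.2`)
  robustly under inter-animal jitter;
* the non-survivor phenotype — lower systemic-activation thresholds
  (0.5 -> 0.35), slower priming (2 -> 3.5 h) and migration (2 -> 5 h),
  stronger migration impairment, delayed anti-inflammation and slow
  damage resolution (48 -> 120 h) — progresses to overwhelming infection
  with sustained `PI > 0.5`.

The homeostatic initial condition places `N_r0 = 8e6` cells/ml resting
neutrophils in blood, with the marrow reserve sized to sustain that pool
(`N_bm0 = N_r0 / (tau_death * k8)`, about 2.5e11).

HA device rates are not physically calibrated; the defaults (N_a: 3e6
cells/ml/hr at K 2e5; PI: 1.5 /hr at K 0.2; AI: 0.1 /hr at K 0.35) were
chosen once so that 10-25 % of a jittered synthetic non-survivor cohort
flips to survivor — the qualitative regime of a partially effective
intervention — and are exposed through `HAConfig`.

## Synthetic cohorts

The generator emulates the structure of a two-cohort septic-rat study:
23 animals (7 survivors), 8 observables, 7 sampling times (18, 22, 48,
72, 120, 144, 168 h). Each animal gets cohort ground-truth parameters
jittered lognormally (sd 0.1 in log10 space, clipped to the prior box);
raw cytokine values are synthesized as `exp(ln(1000) * O)` (three assay
decades) and markers as `O + 1e-4`; multiplicative lognormal assay noise
(sd 0.2 on the log scale) is applied; cytokines are ln-transformed and
every channel is divided by its per-cohort maximum over all animals and
times, so the cytokine pipeline returns the model observable exactly in
the noiseless limit. Per-cohort, per-time means and SDs (floored at
0.05 on the normalized scale) form the calibration target.

What this does *not* emulate: assay detection limits and censoring,
inter-assay batch effects, animal dropout (dead animals keep
contributing until 168 h), and any numerical resemblance to real rat
measurements. Passing calibration and recovery tests therefore shows the
machinery is sound under the stated noise model, not that the model fits
any particular experiment.

## Calibration

Cost is the weighted SSR over all observables and times,
`sum ((m - yhat)/sigma)^2`, with the simulated observables max-normalized
per channel over the measurement grid — the same scale the data live on.
This choice makes the noiseless synthetic problem exactly recoverable
(cost at the generating parameters ~0), at the price of a cost function
that is only piecewise smooth in the normalizing point; the Metropolis
sampler is indifferent to this.

Sampling is plain Metropolis on the log10-parameter scale: uniform prior
box (thresholds 1e-3..1 or 1e4..1e9 by unit, time constants 0.5..500 h,
rates ±1.5 decades around baseline), componentwise normal proposals,
out-of-bounds proposals rejected, target `exp(-C/T)`. The proposal scale
is adapted during burn-in by Robbins-Monro stochastic approximation
toward an acceptance ratio of 0.25 (windows of 100 steps, gain
`2/(1+n)^0.6`) and then frozen, with the chain continuing from the
adapted state so post-freeze samples form a time-homogeneous Markov
chain. The temperature is a configuration value; the default `T = 20`
is sized to the desk-scale calibration problem so that typical proposal
cost increments are of order `T`, which makes the acceptance ratio a
stable function of the proposal scale rather than of the local
ruggedness of the cost landscape (at `T = 1` the frozen-scale acceptance
drifts with the chain's position). Analytic targets and untempered runs
set `T` explicitly. Convergence uses the classic multi-chain
Gelman-Rubin PSRF `sqrt(((n-1)/n W + B/n)/W)`.

Desk-scale defaults (2 chains x 2,000 steps over an 8-parameter mask:
ids 1, 3, 4, 5, 13, 19, 22, 32 — the inflammatory regulation and
neutrophil-kinetics block) keep a full pipeline run at workstation
scale; the `full` preset (5 chains x 1e6 samples, all 34 parameters)
mirrors a cluster-scale study and is never exercised by the tests.

## Ensemble contrast

Analysis operates on log10-scale ensembles pooled across chains
(subsampled to at most 10,000 draws). The inverse correlation matrix
`K = C^-1` serves as the approximate Hessian: its eigenstructure gives
stiff/sloppy directions; `R_i = sqrt(1 - 1/K_ii)` the multiple
correlation; `P_ij = -K_ij/sqrt(K_ii K_jj)` the partial correlation.
Pair changes between two ensembles are tested with a two-sample Fisher z
test using the partial-correlation degrees of freedom `n - 3 - (p - 2)`,
Benjamini-Hochberg corrected at alpha 0.05, plus an absolute-difference
filter of 0.1; significant pairs are classified lose / gain / flip (flip
additionally requires both coefficients individually significant).
Because MCMC draws are autocorrelated, `effective_sample_size` (via the
integrated autocorrelation time) is provided for use as the effective
`n` when testing chain-derived ensembles.

## Numerical choices

* Integrator: LSODA, rtol 1e-6, atol 1 for concentration states (which
  span nine decades) and 1e-9 for unit-interval states. The RHS is
  JIT-compiled with numba when available, with a pure-Python fallback.
* Negative undershoot at roundoff scale is clamped inside the RHS and at
  output; violations beyond 10x the absolute tolerance raise
  `IntegrationError` carrying the offending parameters. During MCMC an
  integration failure maps to infinite cost (proposal rejected).
* Eigenvector sign convention: largest-magnitude component positive.
  Ensemble condition numbers above 1e12 raise `SingularEnsembleError`.
* All randomness flows through `numpy.random.Generator` seeded per
  stage from one master seed (`SeedSequence.spawn`), so every artifact
  is bit-reproducible given its configuration.

## Known limitations

* Baseline parameter values beyond the structural anchors above are
  package choices; they produce the qualitative survivor/non-survivor
  phenomenology, not any particular measured animal.
* The HA device is phenomenological — no flow rates or adsorption
  isotherms; rescue fractions depend on the chosen elimination rates.
* Compartments are well-mixed; there is no spatial transport, no
  explicit cytokine network, and no pathogen heterogeneity.
* Desk-scale chains (10^3-10^4 steps over 8 parameters) demonstrate the
  machinery; they do not produce converged 34-parameter posteriors.
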