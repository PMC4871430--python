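# Methods

## Model

Each individual carries a latent vitality `v`, normalized to `v = 1` at
cohort entry (age 0 on the *model clock*). Two processes end life:

* **Intrinsic**: `v` follows a Wiener process with drift `-r` and diffusion
  `s`; death at the first passage of zero. The age at intrinsic death is
  inverse-Gaussian with mean `1/r` and variance `s²/r³`; its survival
  function is the two-term Φ expression with the `exp(2r/s²)` reflection
  factor.
* **Extrinsic**: environmental challenges arrive as a Poisson process with
  frequency `λ`; magnitudes are exponential with mean `β` (in units of
  initial vitality). A challenge whose magnitude reaches current vitality
  kills, so given vitality `v` a challenge is lethal with probability
  `e^{-v/β}`.

In the full model the two processes interact through the common vitality
path. The fitted *closed form* severs that interaction by giving the
extrinsic process the deterministic path `v(x) = 1 − r·x`, making total
survival a product `l = l_i · l_e` with `l_e` the exponential of the
integrated Strehler–Mildvan hazard `λ e^{-(1-rx)/β}` (log-linear in age,
slope `r/β`). The closed form is evaluated as written beyond `x = 1/r`,
where the linear-vitality approximation has run out but the expression
remains finite and monotone; consequences are discussed under
*Limitations*.

### Parameters

| name | meaning | units | typical magnitude |
|------|---------|-------|-------------------|
| `r` | mean rate of vitality loss | 1/year | ~0.013 (mean intrinsic lifespan `1/r` ≈ 75 y) |
| `s` | variability of vitality loss | year^-1/2 | ~0.013 |
| `lam` (`λ`) | extrinsic challenge frequency | 1/year | ~0.045 |
| `beta` (`β`) | mean challenge magnitude | fraction of initial vitality | ~0.4 |

All four must be positive (`λ = 0` is allowed and disables extrinsic
mortality). The benchmark set used throughout the tests,
`(0.0135, 0.0126, 0.0449, 0.3999)`, is typical of a late-19th-century
European cohort.

### Age origin

Historical cohort data exclude childhood: curves are truncated at age 10
and renormalized to survivorship 1 there. The package's convention is that
the model clock starts at the entry age with unit vitality; fitting shifts
interval breaks so the first break is clock zero. The chronological
convention (vitality 1 at birth, survival conditioned on reaching the
truncation age) is available through `conditional_survival(params, x0, x)`
and is what the synthetic twin study uses when simulating lives from birth
and truncating at 10. The two conventions genuinely differ — entrants at
age 10 do not have exactly unit (nor homogeneous) vitality — and that
mismatch is part of what the bias correction absorbs, for synthetic and
real data alike.

## Individual-based simulator

Euler scheme with step `dt` (default 0.05 y, horizon 120 y):

1. diffusion update `v ← v − r·dt + s·√dt·Z`;
2. intrinsic death if `v ≤ 0`, else a Brownian-bridge draw catches
   within-step crossings (`P = exp(−2 v_prev v_new / (s² dt))`);
3. for survivors, a Poisson(`λ·dt`) challenge count; for individuals with
   `k ≥ 1` challenges the *maximum* magnitude is drawn directly from its
   CDF `(1 − e^{−x/β})^k` and compared to current vitality.

Deaths are recorded at the midpoint of their step (unbiased to O(dt) and
distinct from the horizon-censoring marker `age = max_age`). The fixed
within-step order (diffusion → intrinsic check → challenges) is a
convention whose effect vanishes as `dt → 0`; a step-halving check is part
of the test suite. Each cohort consumes one `numpy` Generator seeded from
its configured seed, with a fixed draw order, so a config reproduces its
records bit-for-bit; per-group seeds in multi-group studies derive
deterministically from the global seed.

### What the synthetic twin study does and does not emulate

`make_twin_study` generates MZ/DZ twin cohorts as pairs (consecutive ids
sharing `pair_id`) and general-population cohorts unpaired, simulated from
birth, with the registry's truncation rule: a pair is retained only if both
members survive the truncation age. Co-twin lifespans are *independent* —
the generator encodes no shared frailty or genetic correlation in age at
death (a test asserts the within-pair correlation is statistically zero).
Passing tests on these data therefore validate the estimation machinery,
not any heritability structure; group differences exist only insofar as the
per-group parameters differ in the configuration. Real registry features
not emulated: migration and loss to follow-up, cohort-to-cohort period
effects (parameters are constant within a group), misclassified zygosity,
and childhood mortality detail below the truncation age.

## Estimation

**Likelihood.** For breaks `b_0 < … < b_m` on the model clock and the
closed-form survival `S`, cell probabilities are
`p_j = (S(b_j) − S(b_{j+1}))/S(b_0)` and `p_open = S(b_m)/S(b_0)`; the
log-likelihood is multinomial with the open cell receiving deaths beyond
the last break plus right-censored survivors. Cell probabilities are
floored at 1e-300 before the log so that line searches degrade gracefully
instead of hitting −∞; invalid parameters raise rather than returning −∞ so
optimizers cannot silently wander out of the domain.

**Optimization** runs on `log θ` (positivity plus the r,s vs λ,β scale
disparity) inside box constraints (`r, s ∈ [1e-4, 1]`, `λ ∈ [1e-7, 5]`,
`β ∈ [1e-3, 10]`): Nelder-Mead from each start, then an L-BFGS-B polish of
the best, `ftol` 1e-8. Default initialization is moment-style — `r₀ =
1/(median death age + 1)`, `s₀ = r₀`, `λ₀` = crude death rate over the
youngest decile of intervals, `β₀ = 0.3` — with five starts (the base and
×3/÷3 perturbations, including intrinsic-vs-extrinsic swaps). A fit that
ends on the parameter boundary is flagged and not reported as converged
(degenerate inputs such as all deaths in one interval end up here).
`exp(2r/s²)` in the intrinsic closed form is combined with the normal
log-CDF in log space; at realistic parameters the exponent alone is ~170,
far beyond direct `exp` range.

**Uncertainty.** The variance matrix is the inverse negative Hessian of the
log-likelihood at the optimum, by central finite differences with relative
step 5e-4 per parameter, symmetrized; a non-PSD result falls back to a
pseudo-inverse and lowers the `vcov_psd` flag. Standard errors scale as
`1/√n` in the cohort size behind the counts, which is why
`cohort_to_interval_deaths` rescales `lx` proportions to the *actual*
cohort size rather than the table's radix (both are supported via
`actual_n`).

**Bias correction.** Fitting the severed closed form to data from the
interacting process reads `r` and `β` low and `s` and `λ` high: near
`x = 1/r` the deterministic-vitality hazard over-kills relative to the true
saturating per-challenge lethality, and the stochastic vitality spread
inflates apparent `s` and `λ` earlier in life. The correction is calibrated
by simulation: a fixed-point iteration `θ ← θ · θ̂_raw / mean(θ̂(θ))`, where
`mean(θ̂(θ))` averages closed-form ML estimates over `B = 50` simulated
cohorts generated at `θ` (at most 5 iterations, stopping at 1% relative
update). The converged `θ*` — the generator whose mean closed-form estimate
is the observed raw fit — is the corrected estimate, and `θ*/θ̂_raw` is a
reusable multiplicative correction map. Calibration cohorts use size
`n_cal = 2000` regardless of the data's size: the bias being corrected is a
model-mismatch effect, essentially independent of `n`, while calibration
cost is linear in `n`. With `B = 0` the correction is the identity (with a
warning). Analyses that refit many subsamples (the bootstrap validation)
calibrate the map once on the full-sample fit and apply it per replicate,
exactly as a fixed set of published correction formulas would be.

## Analysis stages

* `survival_difference`: per-age difference of survival proportions on the
  intersection of the age grids (no interpolation); antisymmetric.
* `decompose`: intrinsic and extrinsic curves at the corrected parameters;
  their product is the fitted total curve to machine precision.
* `compare_parameters`: corrected estimates with ±2·SE intervals (SEs from
  the raw fit's information matrix — the correction is a calibrated
  reparameterization of the same optimum, and the intervals are meant for
  orientation, not formal tests).
* `bootstrap_validation`: per twin group, `B` replicates each drawing
  ⌊0.75·n_pairs⌋ *pairs without replacement* (subsampling, matching the
  validation design it reproduces; the resampling unit is the pair, the
  unit of the retention rule), refitting, applying the group's correction
  map; unconverged replicates are excluded and counted, never imputed.
  General-population records have no pairs and are skipped.
* `parameter_recovery_study`: the end-to-end validation experiment —
  simulate replicate cohorts at known parameters, fit, correct, summarize
  by medians.

## Problem sizes and runtime

Defaults chosen for single-core desk scale: recovery studies use 5
replicate cohorts of n = 10,000 (1-year intervals to age 110, `dt = 0.05`);
the simulator-vs-closed-form comparison uses n = 100,000; bias calibration
B = 50 × n_cal = 2,000; the bootstrap check runs B = 50 at 1,000 pairs
(`--fast`; the full default is B = 1,000). The complete test suite runs in
about five minutes; the recovery script in three to four.

## Limitations

* The closed form is an approximation to the interacting two-process
  model. At the benchmark parameters its total-survival curve deviates from
  the individual-based simulator by a few hundredths of survival
  probability, concentrated near `x = 1/r` (the oracle-equivalence check in
  the acceptance tests measures this directly, and currently sits just
  above its 0.02 target for exactly this reason). The bias correction
  compensates at the parameter level — median corrected estimates recover
  generators to well under 1% — but the corrected *curve* still inherits
  the closed form's shape.
* Standard errors ignore calibration noise in the correction factors
  (ordinarily small: ~1-2% relative, versus parameter SEs of similar or
  larger size at registry-scale cohorts).
* Extrinsic parameters estimated from cohort data average over the periods
  the cohort lived through; no time-varying `λ`, `β` is fitted.
* No shared frailty between co-twins, no covariates, no profile-likelihood
  or Bayesian uncertainty.
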