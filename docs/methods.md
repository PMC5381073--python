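# Methods

## Model and time-stepping

The community is a discrete-time Lotka–Volterra-type map for a
density-limited prey `P` and a predator `C` that grows exponentially on an
alternative (dissolved) resource and on prey. Abundances are cells ml⁻¹ as
double-precision reals (fractional cells are permitted; the model is
deterministic with no demographic stochasticity). One day is 192
iterations of 7.5 min; `steps_per_day × step_minutes = 1440` is enforced.

Daily samples follow the laboratory convention: counts are taken from the
grown culture at transfer time, so the day-*k* sample (`pre_dilution`,
the default) is the state after day *k*'s growth steps, immediately
before the next transfer. Day 0 is the inoculation state; "disturbance on
day *k*" means the transfer at the start of day *k* uses the disturbed
fold. A `post_dilution` convention (sampling the freshly diluted culture)
is available.

### Handling of the daily transfer

The update rule carries a `(1 − d_t)` survival factor in every step, with
`d_t` nonzero once per day. Two conventions are implemented:

- **`transfer` (default).** The transfer is a pure multiplicative event:
  both populations are divided by the fold, and all 192 growth steps run
  undiluted. The predator's no-prey daily factor under the tenfold
  baseline is then `0.1 × 1.012¹⁹² ≈ 0.988` — a slow decline balanced by
  prey consumption, which is what permits the coexistence equilibrium the
  control cultures show.
- **`in_step`.** The dilution is embedded in the first step of the day
  exactly as the update rule is written, so the growth and interaction
  terms apply to the undiluted abundances in that step. This retains
  `(1 − d + r_C) = 0.112` of the predator at a tenfold transfer instead of
  0.1, raising the no-prey daily factor to `0.112 × 1.012¹⁹¹ ≈ 1.093 > 1`:
  the predator then grows without bound in the absence of prey and drives
  it deterministically extinct. Because that contradicts the observed
  coexistence, `in_step` is provided only as a documented model quirk, not
  as the default.

Dilution divides by the fold directly (rather than multiplying by
`1 − rate`) so that a fold-*f* transfer conserves abundances exactly as
`x/f` in floating point. The map can overshoot below zero for extreme
parameter combinations (large `c_P · C`); abundances are physical, so
negative values are clamped to zero and a `ClampingWarning` is emitted
once per run.

## Disturbance regimes

The baseline is a tenfold daily transfer (rate 0.9/day). The press regime
elevates the fold to 40 on days 22–31 inclusive — ten disturbed transfer
events, with the baseline resuming on day 32; reading the window this way
keeps the stated 10-day duration, and the endpoint convention is
configurable. The pulse regime is a single 2500-fold event on day 15.
"Fold" and "rate" are kept distinct throughout the API because the two
scales differ by the nonlinear map `d = 1 − 1/f` (the press is a 4×
increase in fold, equivalent to a rate change from 0.9 to 0.975).

## Calibration

Stage one fits growth curves sampled at hours 12–24 (every 2 h) of a 24 h
undiluted run, started from 4 × 10⁶ prey and 2.5 × 10³ predator cells ml⁻¹:
(r_P, K_P) from the prey-only culture, r_C from the axenic predator
culture, then (c_P, c_C) from the co-culture with the single-species
estimates fixed. The optimizer is Nelder–Mead in log-parameter space
(all parameters are positive scales; log space prevents sign flips in the
derivative-free search), with three jittered restarts, a 2000-evaluation
cap per stage, and tight tolerances (`xatol 1e-10` in log space,
`fatol 1e-30`) because noise-free synthetic data have an exact
zero-residual optimum. Default search bounds are wide positive ranges
(e.g. r_P ∈ [10⁻³, 1], K_P ∈ [10⁶, 10¹⁰]). After each stage every fitted
parameter is probed at ±10 %; a parameter whose perturbation leaves the
objective numerically flat is reported with an `IdentifiabilityWarning`
(e.g. r_P when the prey curve starts at carrying capacity).

The objective is the summed per-point fourth power of relative distances,
`Σᵢ |(modelᵢ − obsᵢ)/obsᵢ|⁴`, over every replicate count of every
compared species (counts are compared individually, not as replicate
means). The per-point reading is used because raising an L1 sum to the
fourth power would be monotone in the L1 sum and the exponent would have
no effect on the optimum; the exponent is configurable and must be even.
Zero observed counts are excluded with a warning (relative distance
undefined).

Stage two draws a Latin hypercube (`scipy.stats.qmc`) of 500 candidates in
the box ±20 % around the stage-one estimates (both settings configurable
and recorded), simulates the control regime for every candidate in a
single vectorized batch, and selects the candidate minimizing the same
objective over all control replicate counts of both species. The start
point is always evaluated alongside the hypercube, so the selected
objective never exceeds the start's. A freeze mask can hold any subset of
the five parameters fixed; all are refloated by default. The sampler seed
is recorded in the result for exact reproducibility.

## Evaluation metrics

- **Nash–Sutcliffe efficiency** `E = 1 − Σ(obs − pred)²/Σ(obs − ō)²`;
  1 is a perfect fit, 0 the observed-mean predictor; undefined (an error)
  for zero observed variance.
- **Equilibrium band**: the min–max envelope of daily values over day 7 to
  the disturbance start (replicate means for observed data). The plain
  min–max reading of a "range of equilibrium sizes" is used rather than
  mean ± k·sd; with the reference parameters the approach to equilibrium
  is a damped oscillation that has not fully settled by day 22, so bands
  from inoculated runs are realistically wide.
- **Response time**: days from disturbance start to the first sample
  outside the band; `None` (undefined, never fabricated) if the series
  stays inside.
- **Recovery time**: days from disturbance end to the return to
  pre-disturbance size. Two criteria are provided: `band` (first sample
  inside the band — first single day, with an optional persistence-free
  tolerance) and `reach` (first crossing of the band edge from the deficit
  side). The crossing criterion is the default in scenario and sweep
  runners because a predator regrowing at up to ×3.6/day can step over a
  narrow band between daily samples, which would make recovery times
  erratically long; "reaching the pre-disturbance size" is the quantity
  the sweeps are about. Censoring is explicit: if the series ends before
  return, the result carries the observed horizon and a flag.
- **Deviation time D_T**: model response (or recovery) time minus that of
  the replicate-mean observed series; negative D_T means the model
  responds earlier. Undefined if either side is undefined.
- **Prey-release covariance**: the sample covariance (ddof = 1) of the two
  series over a day window after rescaling each series by its own maximum
  over the full experiment. Raw covariances of counts spanning 10³–10⁸
  cells ml⁻¹ would be astronomically scaled; max-scaling makes windows and
  treatments comparable while preserving sign. z-score, log₁₀ and raw
  scalings are available; the normalization is a package choice and the
  "before" window is the band window, the "during/after" window runs from
  the first disturbed day until both species have re-entered their bands
  (or the series ends).

## Scenario and sweep design

Scenario presets mirror the experimental protocols: control and press
start from 3.6 × 10⁷ prey and 4.2 × 10⁴ predator cells ml⁻¹, the pulse
from 4 × 10⁶ and 4 × 10³ (same ratio, lower density).

Sweeps (press duration 2–12 d at fold 40; pulse fold 10–10⁶ on a decade
grid; r_C 0.007–0.011 under a 2500-fold pulse) emulate disturbing
communities that have reached equilibrium: each run first equilibrates
under the baseline regime (150 burn-in days by default — the damped
oscillations decay slowly, and for swept r_C values the equilibrium
itself differs from the inoculum) and then applies the disturbance on day
22. Because a fully equilibrated pre-disturbance band has near-zero
width and the post-disturbance approach is asymptotic, sweep recovery
uses the `reach` criterion with a 2 % relative band tolerance. The
post-disturbance horizon is 60 days (120 for the r_C sweep, whose weakest
coupling needs ~56 days); censored runs are reported as censored, never
extrapolated. Populations dipping below a 1 cell ml⁻¹ floor are flagged
as at extinction risk — the deterministic map cannot reach exact zero, so
the floor makes extinction statements operational.

Each run's band is computed from that run's own pre-disturbance days;
across the r_C sweep the bands therefore shift with the per-value
equilibria (weaker coupling, lower predator equilibrium).

## Synthetic data

The generator emulates the study design: triplicate daily counts around a
deterministic trajectory, and the three growth-curve setups (prey-only,
axenic predator, co-culture) sampled at hours 12–24. Replicate noise is
multiplicative lognormal with mean exactly 1 (`σ² = ln(1 + cv²)`, location
`−σ²/2`); the default cv of 0.1 is a typical day-to-day spread for
microscopy/particle-counter counts of microbial cultures. `cv = 0`
reproduces the deterministic series bit-for-bit, which anchors the
parameter-recovery tests. The generator does not emulate counting-method
artifacts (detection thresholds, fixation losses), diurnal environmental
variation, or any real-data departures from the model family itself — so
passing recovery tests demonstrate the estimator pipeline is correct and
well-conditioned under the assumed noise structure, not that the model is
adequate for any particular real culture. An optional switch rounds
counts to whole cells for stress tests.

## Numerical choices and limitations

Delimited outputs are written with 17-significant-digit floats and read
back with round-trip parsing, so file round trips are exact. Batch
candidate simulations tolerate overflow (diverging candidates become
non-finite and are assigned an infinite objective; a batch in which every
candidate diverges is an error naming the first overflow). Problem sizes
throughout (22–200-day runs, 500-candidate refinements, 11-value sweeps)
run in seconds on one core.

Known limitations: the functional response is linear (no saturation —
Holling II/III responses, resource-explicit chemostat dynamics, and
density-dependent coupling of r_C are out of scope); one disturbance
window per run; the equilibrium-band and covariance normalization
conventions are package choices among several defensible readings and are
exposed as options rather than hidden.
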