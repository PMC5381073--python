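# microlv

Transient recovery dynamics of a serially diluted microbial predator–prey
microcosm under press and pulse disturbances.

The package is aimed at ecologists and modellers studying how disturbance
strength, duration, and a predator's coupling to an alternative resource
shape the transient response and recovery of a simple two-species food
web — a density-limited bacterial prey (*E. coli*-like) grazed by a
protist predator (*Tetrahymena*-like) that can also grow osmotrophically
on dissolved nutrients, maintained by daily serial transfers.

## Model

Abundances (cells ml⁻¹) are iterated at a 7.5-min step, 192 steps per day:

```
P[t+1] = (1 − d[t]) P[t] + r_P P[t] (1 − P[t]/K_P) − c_P P[t] C[t]
C[t+1] = (1 − d[t]) C[t] + r_C C[t] + c_C P[t] C[t]
```

where `P` is prey, `C` the predator, `r_P` and `K_P` the prey's growth
rate and carrying capacity, `r_C` the predator's growth rate without prey
(its coupling to the alternative resource), `c_P` and `c_C` the
interaction coefficients, and `d` the dilution mortality applied once per
24 h (a fold-*f* transfer retains 1/*f* of the culture, d = 1 − 1/f).
Reference values: r_P = 0.094, r_C = 0.012 per step, K_P = 4.9 × 10⁸,
c_P = 3.5 × 10⁻⁶, c_C = 1.4 × 10⁻¹¹.

On top of the tenfold daily baseline, a **press** disturbance is a 40-fold
daily dilution sustained for 10 days (days 22–31) and a **pulse** is a
single 2500-fold event (day 15). Evaluation uses the Nash–Sutcliffe
efficiency E = 1 − SSE/SST, the pre-disturbance equilibrium band (min–max
of daily abundances from day 7 to disturbance start), response time (days
until a population leaves its band), recovery time (days from disturbance
end until it returns), deviation time D_T (model minus data), and the
windowed prey–predator covariance whose increasingly negative values
diagnose *prey release*.

Calibration is two-staged: Nelder–Mead fits of (r_P, K_P), r_C, and
(c_P, c_C) to 24 h growth curves, then Latin-hypercube refinement of the
full parameter set against control counts under the objective
Σᵢ |(modelᵢ − obsᵢ)/obsᵢ|⁴.

## Worked example

```python
import microlv as m

# press disturbance scenario: 40-fold daily dilution on days 22..31
result = m.run_scenario(*m.press_scenario())
pred = result.metrics["predator"]
print(pred.band.low, pred.band.high)     # 56722.4 60127.7
print(pred.response, pred.recovery.days) # 0 6
print(result.cov_before)                 # -2.76e-06
print(result.cov_during_after)           # -0.185
```

The predator's pre-disturbance equilibrium band is (5.67 × 10⁴,
6.01 × 10⁴) cells ml⁻¹; it falls below the band on the first disturbed day
(response time 0) and crosses back 6 days after the press ends. The
prey–predator covariance is near zero before the disturbance (−2.8 × 10⁻⁶)
and strongly negative during/after it (−0.185): the prey is transiently
released from predation while the predator is suppressed.

Sweeping the disturbance axes (each run starts from the equilibrated
community):

```python
m.sweep(m.press_duration_sweep()).recovery_series("predator")
# press duration 2..12 d  -> predator recovery 3, 3, 4, ..., 7 d (non-decreasing)
m.sweep(m.pulse_fold_sweep()).recovery_series("predator")
# pulse fold 10..1e6      -> recovery 0, 3, 5, 8, 10, 12 d (1e6 flagged: predator
#                            dips below 1 cell/ml, an extinction-risk marker)
m.sweep(m.r_c_sweep()).recovery_series("predator")
# r_C 0.007..0.011        -> recovery 56, 26, 16, 11, 8 d (stronger coupling to
#                            the alternative resource speeds recovery)
```

A command-line pipeline wraps the same functionality:

```sh
microlv fixtures --outdir fx --cv 0.1 --seed 0      # synthetic datasets
microlv simulate --config press.yaml --outdir out   # trajectory + metrics
microlv calibrate --config cal.yaml --growth-curves fx/growth_curves.csv \
    --control-counts fx/counts_control.csv --outdir cal
microlv sweep --config sweep.yaml --outdir sw
```

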