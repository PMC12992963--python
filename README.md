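# timingpriors

Simulation and analysis of **multiple-prior acquisition in coincidence
timing tasks**, for psychophysicists studying Bayesian interval timing.

In these experiments a stimulus interval T_S is drawn on every trial from
one of two discrete uniform priors — short (450–1050 ms, μ = 750 ms) and
long (1200–1800 ms, μ = 1500 ms) — presented in alternation and cued by
color, and the participant reproduces the interval with a timed button
press (T_R), optionally adding a concomitant motor response (CMR) for one
prior. The scientific question is whether participants acquire **two
independent priors** or **one generalized prior**, and whether a CMR
facilitates the former.

The analysis rests on a Bayesian observer with scalar variability
(σ_sensed = w·T_S): the mean reproduction is

```
T̄R(T_S) = a·T_S + (1 − a)·μ_prior,   a = σ²_prior / (σ²_prior + w² T_S²)
```

so responses regress toward the acquired prior mean, more strongly for
longer intervals, and the T̄R × T_S curve crosses the unity line exactly
at μ_prior. The package provides:

* `observer` — the shrinkage curve, prior moments, unity-line identities;
* `design` — alternating two-prior trial schedules with counterbalancing;
* `cohort` — synthetic participants generating trial-level responses
  (sensory + motor noise, merged or independent acquired priors, biases,
  lapses, CMR lags);
* `preprocess` — erroneous-trial exclusion, ±3 SD outlier removal,
  per-bin binned means T̄R and grand averages;
* `fitting` — exact profiled least-squares fits of the two-prior and
  one-prior curves, the T̄R(Μ_priors) and μ̂ metrics, undershoot
  compensation;
* `inference` — AICc / Akaike-weight model comparison and a
  label-permutation test for between-experiment differences in Δμ̂;
* `pipeline` / `cli` — configuration, orchestration, tabular I/O.

See `docs/methods.md` for the model, estimation and design choices.

## Worked example

Simulate a 20-participant experiment whose observers acquired two
independent priors, then analyze it:

```
$ timingpriors simulate --seed 7 --out demo/sim
$ timingpriors analyze --trials demo/sim/trials.csv --out demo/out
bin 1: mu_hat short/long = 750.9/1500.6 ms, delta TR_bar(M_priors) = 270.7 ms, Akaike w(one/two) = 0.00/1.00
bin 2: mu_hat short/long = 738.1/1495.3 ms, delta TR_bar(M_priors) = 259.0 ms, Akaike w(one/two) = 0.00/1.00
```

Reading the output: for each 320-trial bin, the two-prior curves fitted to
the grand-averaged T̄R values cross the unity line near 750 and 1500 ms —
the acquired prior means (μ̂) recover the generating ones. The two curves
evaluated at the midpoint of the prior means (Μ_priors = 1125 ms) differ
by ~260–270 ms (ΔT̄R(Μ_priors) > 0), and the Akaike weights put
essentially all evidence on the two-prior model: this cohort acquired two
independent priors. A merged cohort would instead show ΔT̄R(Μ_priors) ≈ 0,
Δμ̂ ≈ 0 and the one-prior model winning.

The same operations are available as library calls
(`simulate_trials`, `preprocess`, `fit_two_prior`, `eval_metrics`,
`compare_models`, `permutation_test`), and
`timingpriors reproduce --out dir` runs a full two-experiment
(CMR vs control) comparison including the permutation test.

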