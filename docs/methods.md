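# Methods

## The model

`timingpriors` analyzes coincidence-timing experiments in which a stimulus
interval T_S is drawn on every trial from one of two discrete uniform
priors — short (450, 600, 750, 900, 1050 ms; μ = 750 ms) and long (1200,
1350, 1500, 1650, 1800 ms; μ = 1500 ms) — presented in strict alternation
and cued by color. A participant reproduces the interval with a timed
button press (response interval T_R), optionally accompanied by a
concomitant motor response (CMR) for one of the priors.

The observer is modeled as a Bayesian estimator under scalar variability:
the sensed interval has SD σ_sensed = w·T_S (Weber fraction w), and the
mean reproduction is a precision-weighted convex combination of stimulus
and acquired prior mean,

    T̄R(T_S) = a·T_S + (1 − a)·μ_prior,   a = σ²_prior / (σ²_prior + w²T_S²).

Because a falls with T_S, responses regress toward μ_prior more strongly
for longer intervals, and the T̄R × T_S curve crosses the unity line
exactly at μ_prior. Only μ_prior and the ratio r = σ_prior / w are
identified by a single curve: rescaling (σ, w) → (cσ, cw) leaves it
unchanged.

Whether a participant acquired two independent priors or one generalized
prior is read off two metrics derived from fitted curves:

* **T̄R(Μ_priors)** — each prior's fitted curve evaluated at the midpoint
  of the two prior means (Μ_priors = 1125 ms). The evaluation point lies
  outside both priors' stimulus ranges; the extrapolation is the point of
  the metric. Two independent priors make the long-prior value exceed the
  short-prior value (ΔT̄R(Μ_priors) > 0); a generalized prior makes the
  curves overlap.
* **μ̂_prior** — the fitted μ of each branch, identically the curve's
  unity-line crossing. Δμ̂ = μ̂_long − μ̂_short.

## Curve fitting

Two nested models are fitted by ordinary least squares to (T_S, T̄R)
points: the two-prior model (per-branch μ and σ, shared w; 5 nominal
parameters) and the one-prior model over the full range (3 nominal
parameters). Because each curve identifies only (μ, r), the shared-w
constraint is vacuous at the curve level, and the two branches can be fit
independently without changing the optimum.

For fixed r the model is linear in μ, so μ is profiled in closed form and
the profiled RSS is minimized over log10 r by staged grid refinement
(search range r ∈ [1, 10⁷] ms, 85-point coarse grid, three 17-point local
refinements, final parabolic step; terminal resolution ≈ 2×10⁻⁴ in
log10 r). This is exact least squares on the identified parameters, fully
deterministic, an order of magnitude faster than generic optimizers (the
permutation test fits hundreds of thousands of curves), and — by
construction — independent of initial values, which the identified
quantities μ̂, T̄R(Μ_priors) and RSS must be. Initial values
(μ = 750/1500 ms, σ = 237 ms, w = 0.15 for the two-prior model;
1125 ms / 454 ms / 0.15 for the one-prior model — the true design moments
under the n−1 SD convention) enter only through the nominal Weber
fraction, from which the non-identified σ values are back-computed
(σ = r·w_nominal). Reported σ and w therefore rescale with the chosen
nominal w while μ̂ and all curve evaluations do not.

Fits are unconstrained in μ: implausible μ̂ values (outside the 450–1800 ms
stimulus range) are flagged *irregular*, never clipped, because
idiosyncratic response patterns (undershoots, slopes above unity) really
do drive the unity crossing to extreme values. Data exactly on the unity
line are non-identifiable and raise an error rather than returning
numbers. An optimum at the edge of the ratio search range marks a
near-degenerate curve (`at_bound`).

### Undershoot compensation

A systematic undershoot can push the short-prior unity crossing far
outside the plausible range. When that happens (policy `auto`; `always`
and `never` are available), the constant bias is estimated as the mean of
T̄R − T_S over the bin's ten grand-averaged points, subtracted, and the
curves refit. The compensated μ̂ pair is then re-anchored by the long
prior, whose fit is regular with or without compensation: with
d = μ̂_long(compensated) − μ̂_long(original), both compensated values are
shifted by −d, leaving the long-prior value exactly at its original fit.
Note the bias estimate deliberately includes the curves' own
central-tendency offset (≈ −20 ms under the canonical parameters even
with no motor bias); it measures the data's total systematic deviation
from the unity line, not the generative motor bias alone.

## Preprocessing

Trials are excluded in a fixed order, then averaged:

1. validity — no timing press, multiple presses of the same control,
   missing CMR when required, or an unrequired CMR ("erroneous responses"
   are defined as exactly the error modes the task affords);
2. outliers — responses strictly outside mean ± 3 SD per (participant,
   320-trial bin, T_S), computed over valid trials only, n−1 SD, single
   pass, boundary values retained; cells with fewer than 3 valid trials
   skip the rule with a warning;
3. binned means T̄R per (participant, bin, prior, T_S) — 2 × 2 × 5 cells
   of 32 trials each under the default balanced design — and unweighted
   grand averages across participants.

Bin boundaries are fixed by trial index (1–320, 321–640), and the ± 3 SD
statistics are computed after removing erroneous trials.

## Inference

**AICc / Akaike weights.** For each bin, both models are fitted to the
grand average, and every participant's binned mean contributes a residual
from the fitted curve (n = 20 × 10 = 200). Under a Gaussian likelihood,
AICc = n·ln(RSS/n) + 2K + 2K(K+1)/(n−K−1). By default K counts the
residual variance (K = k+1, i.e. 6 vs 4); the K = k convention is a flag,
since the two differ negligibly at n = 200. Akaike weights are
exp(−Δᵢ/2) normalized after a min-shift (overflow-safe).

**Permutation test.** To compare Δμ̂ between a test and a control
experiment, each participant's per-bin T̄R profile (10 values) is pooled
across the two groups; labels are reassigned at random preserving the
20/20 sizes; each relabeling is grand-averaged per label, curve-fitted
(with the same bias-compensation policy as the observed analysis — the
policy must match for exchangeability), and scored by
Δμ̂(test) − Δμ̂(control). p is the fraction of permutation differences
strictly exceeding the observed one (so p = 0 is attainable), reported
against the Bonferroni-corrected α = 0.05/2 for the two bins, which are
permuted independently. Iterations with irregular μ̂ (default |μ̂| >
10 000 ms; the stricter outside-[450, 1800] rule is a flag) are removed
and counted, and excluded from the denominator; a no-removal mode is also
provided. Small groups can be tested by exhaustive enumeration of all
size-preserving splits.

## Synthetic cohorts

The generator emulates the study conditions: 20 participants × 640 trials
(16 sessions of 40), alternating priors, balanced T_S counts (32 per
value per prior per bin; an iid sampling mode exists because the original
balance is not knowable from the design alone), counterbalanced
prior–color and CMR–color pairings (4 combinations).

Each simulated observer holds acquired prior means μ̂_short/μ̂_long, a
per-bin merge fraction λ interpolating between independent priors (0) and
one generalized prior at Μ_priors (1) — allowing divergence to emerge
between bins, as observed after a few hundred trials of learning — plus
shrinkage ratios r per prior, Weber fraction w, additive motor noise,
constant timing bias, lapse rate, and a Gaussian CMR lag. A valid trial
applies the shrinkage rule to the *sensed* interval t_m ~ N(T_S, (wT_S)²)
(floored at 1 ms), then adds motor noise and bias. Averaging over t_m
reproduces the mean-level curve up to a small Jensen-type offset (≲ 20 ms
at the longest intervals under the canonical parameters, verified against
a Gauss–Hermite quadrature oracle); with w = 0 the Bayesian weight on the
measurement is 1 and responses are exact. Lapse trials draw one of four
switchable error modes (duplicate press, missing/extra CMR, no response)
to exercise the exclusion rules.

Canonical population defaults: w = 0.15 ± 0.03 (literature-scale),
r = 237/0.15 ms per prior ± 300, acquired means at the true prior means
± 100 ms, motor SD 50 ± 15 ms, no bias, no lapses, CMR lag 20 ± 10 ms.
Inter-participant SDs are modeling choices, not claims about the
population; parameter-recovery checks use a homogeneous cohort at the
canonical values so that recovery error reflects the estimator, not
cohort sampling. What passing tests show is that the pipeline recovers
the structure this generator produces; real data add idiosyncrasies the
generator only caricatures (learning drift within bins, non-Gaussian
lapses, sequential dependencies), which is why irregular-μ̂ handling and
undershoot compensation exist.

## Problem sizes and numerical choices

* Parameter recovery: 20 participants × 640 trials; grand-average μ̂
  recovered within ±50 ms of the generating means (a systematic ≈ −30 ms
  shrinkage-on-sensed-interval offset in μ̂_long is part of this band).
* Permutation calibration: 200 simulated null replicates with n_perm =
  1000 give a rejection rate of 2.5% ± 1.5% at α = 0.025; 40 replicates
  with a planted 750 ms Δμ̂ difference are detected essentially always.
  Monte-Carlo p agrees with exhaustive enumeration on 3-vs-3 groups.
* Optimizer: exact profiled LS; ratio grid as above; ties broken toward
  the smaller grid index by argmin; degenerate denominators floored at
  1e−300.
* All intervals are in milliseconds, floating point, everywhere.

## Known limitations

* μ̂ from individual fits is noisy (the unity crossing is an
  extrapolation); it is reported from grand-average fits only, and
  per-participant output is intended for the T̄R(Μ_priors) comparisons.
* The one-/two-prior AICc comparison on a merged-prior cohort is a small
  margin (penalty difference ≈ 4 at n = 200) sitting on the
  between-participant noise floor; with little inter-participant
  variability it approaches a coin flip even when the generating prior is
  truly merged.
* The generator models learning as a per-bin merge fraction, not a
  trial-by-trial process; within-bin drift is absent by default.
* Cognitive-load and cue-modality effects (color vs spatial cues,
  alternating vs random prior order) are out of scope.
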