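# Methods

## Problem and estimands

A device's failure proportion at a fixed horizon τ (default 10 years) is
compared against an external benchmark proportion `p_bm` (default 5%). Two
estimands must be distinguished as soon as patients can die before τ:

* **Net failure** — the probability the device would fail by τ if death could
  not pre-empt failure (a hypothetical "immortal cohort"). Estimated by
  1−Kaplan-Meier with deaths treated as non-informative right-censoring.
* **Crude failure** — the real-world probability that failure is observed by
  τ, acknowledging that death removes the device from risk. Estimated by the
  non-parametric cumulative incidence function (CIF, Aalen-Johansen).

The benchmarking decision is one-sample non-inferiority: non-inferior iff the
upper bound of the two-sided (1−2α) CI satisfies `upper ≤ p_bm + δ`, boundary
inclusive; δ = 0 is the superiority test. The performance engine scores every
estimator against the **net** truth, which is exactly how the CIF's
systematic deficit (≈0.55 percentage points under the default parameters,
computed by quadrature of `∫₀^τ f_fail(t)·S_death(t) dt`) is exhibited; the
true crude value is carried alongside in the output for reference.

## Data-generating processes

Cause-specific times are Weibull, `S(t) = exp(−λ t^γ)`, sampled by inverse
transform `T = (−ln U/λ)^{1/γ}`:

| parameter | default | meaning |
|---|---|---|
| failure λ, γ | 0.01, 0.71 | 5.0% net failure at 10 y, decreasing hazard |
| mortality λ, γ | 0.017, 1.32 | 29.9% mortality at 10 y, increasing hazard |
| horizon τ | 10 y | administrative censoring time |
| repetitions | 1000 | MC error of a 95% coverage estimate ≈ 0.7% |
| benchmark p_bm | 0.05 | margins δ = 1…5%, one-sided α = 0.025 |

`NCR` draws failure times only; `CR` draws independent failure and death
times per subject (latent-times construction) and observes
`min(T_f, T_d, τ)`. Simulated cohort sizes follow the study grid
n ∈ {100, 200, 400, 800, 1600, 3200, 6400}. These defaults emulate an elderly
arthroplasty registry population; they do **not** emulate loss to follow-up,
staggered entry, correlated (informative) competing risks, or covariate
structure — conclusions from passing tests are confined to the
independent-risks, complete-follow-up regime.

Conventions, chosen once: exact ties `T_f = T_d` (probability ~0 in floats)
resolve to failure, which counts against the device; the observation window
is closed at τ, so an event at exactly τ is an event, not a censoring; times
are kept at full float precision.

## Estimators and confidence intervals

All three estimators share one risk table (distinct times t_j, at-risk n_j
counting subjects with observed time ≥ t_j, per-cause event counts).

* **Proportion**: failures / (n − observed deaths), Wald CI clipped to [0,1],
  no continuity correction (the z-test form of the decision rule). Subjects
  whose failure was observed are failures regardless of later death — under
  the min() observation scheme a post-failure death is never recorded.
* **1−KM**: product-limit over failure events, deaths censored. CI by normal
  approximation on log(−log Ŝ(τ)) with Greenwood variance, back-transformed —
  range-respecting by construction.
* **CIF**: Aalen-Johansen sum with the all-cause KM survivor evaluated just
  before each event time. Variance is the Marubini–Valsecchi (Aalen-type
  counting-process) form — the estimator used by Stata's `stcompet` — and the
  CI is built on the log(−log F̂) scale for symmetry with the KM interval.
  The choice of CIF variance is the one genuinely open design decision here
  (no single convention dominates); the cloglog transform keeps all three
  intervals range-respecting and comparable in width.

Degenerate inputs: a cohort with zero observed failures yields point 0 with
CI [0, 0] and a `degenerate` flag; performance summaries count such
repetitions (they never cover a positive truth and satisfy every margin) and
report the count so their influence is auditable (~1% of repetitions at
n=100, none by n=800). A cohort in which everyone fails yields point 1 with a
zero-width CI. A cohort in which everyone dies leaves the proportion
undefined and raises.

## Performance measures

Per scenario × method, over i = 1…reps with truth P: bias = mean(P̂_i − P);
rmse = sqrt(mean((P̂_i − P)²)); mean_abs_error = mean|P̂_i − P|; coverage = %
of CIs containing P; mean CI width; power(δ) = % of repetitions with
`upper ≤ p_bm + δ`. Both rmse and mean_abs_error are reported because the two
are often conflated in applied summaries: for an unbiased, approximately
normal estimator the absolute-error metric is smaller by the factor
sqrt(2/π) ≈ 0.80, a distinction that matters when quoting "error ≈ 0.46%"
versus "≈ 0.59%" for KM at n=1600 under mortality censoring (both are the
same simulation; the CI width ≈ 2.3% is consistent with the latter as an RMS
and the former as a mean absolute deviation).

## Reproducibility

Every repetition uses its own `numpy` SeedSequence substream spawned from the
scenario seed, so scenarios are bit-reproducible and repetitions independent
of execution order; grid cells derive their seeds from the master seed and
the (n, DGP) coordinates, making any subset of the grid reproduce the full
run's rows. Results files carry a manifest sidecar (version, grid hash,
seeds) sufficient to re-run them exactly.

## Numerical notes and limitations

* The analytic power/sample-size formulas use double-precision normal
  quantiles; sample sizes are ceiling-rounded, so the round-trip
  `power(n(power)) ≥ power` holds everywhere on the δ × power grid.
* The analytic normal-approximation power can differ from the exact binomial
  power of the Wald decision rule by >5 percentage points at small n and
  margins other than 3% (discreteness of the failure count); the test suite
  therefore validates the simulation against an exact binomial oracle at
  every margin and against the closed form at the 3% anchor.
* Quadrature for the true crude failure uses adaptive `scipy` integration of
  the competing-risks integral; the failure density's integrable singularity
  at t=0 (shape < 1) is handled by the adaptive rule to ~1e-9 accuracy.
* Out of scope: covariate adjustment or stratified benchmarking, informative
  or correlated competing risks, loss to follow-up other than administrative
  censoring, sequential/multiple-look monitoring, exact (Clopper-Pearson) or
  score-interval designs.
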