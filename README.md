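# nibench

Design and evaluation of **one-sample non-inferiority benchmarking studies**
of medical-device failure against an external performance benchmark, with
arthroplasty (joint-replacement) prostheses as the motivating setting.

Regulators and implant-rating bodies compare a device's 10-year failure
proportion against an external benchmark such as "at most 5% failure at 10
years", but rarely say *how* the comparison should be made or how many
implants must be observed. `nibench` frames the comparison as a one-sample
non-inferiority test and provides, for statisticians and registry analysts:

* **analytic sample-size and power calculations** for one proportion,
* a **two-cause Weibull cohort simulator** (device failure, with or without an
  independent mortality competing risk, administratively censored at the
  benchmarking horizon),
* three **failure estimators** with 95% CIs — the simple proportion (z-test),
  1−Kaplan-Meier (net failure), and the non-parametric cumulative incidence
  function (crude failure),
* a **Monte-Carlo engine** reporting bias, RMSE, mean absolute error,
  coverage, CI width and power per non-inferiority margin.

## The statistical core

With benchmark failure proportion $P_{BM}$, non-inferiority margin $\delta$
and a device failure estimate $\hat P_F$ with two-sided $(1-2\alpha)$ CI, the
device is declared **non-inferior** when

$$\hat P_{F.upp} \le P_{BM} + \delta ,$$

and $\delta = 0$ recovers the superiority test. For the one-proportion z-test
the cohort size needed at the start of the study to reach power $1-\beta$ is

$$n = \hat P_F (1-\hat P_F)\left(\frac{z_{1-\alpha}+z_{1-\beta}}{\hat P_F - P_{BM} - \delta}\right)^{2},$$

ceiling-rounded. The simulator draws cause-specific event times from
$T \sim \mathrm{Weib}(\lambda, \gamma)$ with $S(t)=\exp(-\lambda t^{\gamma})$;
the defaults ($\lambda=0.01, \gamma=0.71$ for failure; $\lambda=0.017,
\gamma=1.32$ for death) give 5% failure and 30% mortality at 10 years, in line
with national joint-registry experience. Estimators: $\hat P_F = f/n$ (deaths
excluded from the denominator), $1-\hat S(t)$ with
$\hat S(t)=\prod_{j\mid t_j\le t}(n_j-f_j)/n_j$ and a log(−log) Greenwood CI,
and $\widehat{CIF}_k(t)=\sum_{j \mid t_j\le t}\hat S(t_{j-1})\,d_{kj}/n_j$ with a
delta-method CI on the same scale.

## Worked example

How many implants are needed to show non-inferiority against a 5% benchmark
with a 3% margin?

```bash
$ nibench samplesize --margin 0.03 --power 0.5 --power 0.9
p_bm,p_f,margin,alpha_one_sided,power,n
0.05,0.05,0.03,0.025,0.5,203
0.05,0.05,0.03,0.025,0.9,555
```

203 implants give a 50:50 chance of demonstrating non-inferiority when the
device truly performs exactly at the benchmark; 555 give 90%.

How do the three estimators behave at n=1600 when 30% of patients die before
10 years?

```python
from nibench import *

cfg = ScenarioConfig(n=1600, dgp=Dgp.CR,
                     mortality_params=DEFAULT_MORTALITY_PARAMS,
                     reps=1000, seed=1)
print(summaries_to_frame(run_scenario(cfg, BenchmarkSpec())))
```

```
    method    n    bias   rmse  mean_abs_error  coverage_pct  ci_width_mean  power_pct_margin_0.01  power_pct_margin_0.03
PROPORTION 1600  0.0129 0.0147          0.0130          58.0         0.0282                    1.3                   65.1
        KM 1600  0.0002 0.0058          0.0046          96.0         0.0230                   31.9                   99.4
       CIF 1600 -0.0054 0.0074          0.0061          83.3         0.0202                   78.4                  100.0
```

Read against the 5% *net* failure truth: the z-test over-estimates failure
(deaths shrink its denominator, bias +1.3 points, coverage collapses to 58%),
the cumulative incidence function under-estimates it by ~0.5 points (it
answers the crude-failure question), while 1−KM is unbiased (bias 0.02
points, nominal 96% coverage, mean CI width 2.3%, mean absolute error 0.46%)
— but still only ~32% power at a 1% margin even with 1600 implants.

A full study grid is driven by a YAML config (see
`examples/benchmark_grid.yaml`):

```bash
nibench simulate --config examples/benchmark_grid.yaml --out results.csv
nibench evaluate my_cohort.csv --p-bm 0.05 --margin 0.03   # your own registry extract
```

`evaluate` consumes a `time,event` CSV (event ∈ failure/death/censored, times
in years) and emits each estimate with its per-margin decision.

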