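# pilotsize

How large does an external pilot randomised controlled trial (RCT) need to
be?  An external pilot is a small trial run before a definitive RCT whose
data inform its design — above all the standard deviation (SD) of a
continuous outcome, or the event rate of a binary one — but are not pooled
into its analysis.  Estimates from small pilots are imprecise and slightly
biased, and that imprecision propagates into the definitive trial's sample
size and power.  `pilotsize` quantifies exactly how, for trialists and
biostatisticians choosing a pilot size.

## The model

**Continuous outcomes.** A balanced two-arm pilot with *n* subjects per arm
yields per-arm sample variances s₁², s₂² and the pooled SD

    SD_p = sqrt((s₁² + s₂²) / 2),    df = 2(n − 1).

Under normality, df·SD_p²/σ² ~ χ²_df, which gives everything in closed form:

* the mean of the estimator, E[SD_p] = σ·sqrt(2/df)·Γ((df+1)/2)/Γ(df/2)
  (hence its bias);
* two-sided confidence limits SD_p·sqrt(df/χ²_{1−a/2,df}) and
  SD_p·sqrt(df/χ²_{a/2,df}), whose mean width measures precision;
* the one-sided inflation factor sqrt(df/χ²_{1−c,df}) (Browne's adjustment),
  which turns SD_p into its upper confidence limit at confidence c before
  the definitive-trial calculation.

The definitive two-arm trial targeting a standardized effect δ at two-sided
level α and power 1−β is sized with the normal-approximation formula
n = ⌈2(z_{1−α/2} + z_{1−β})²·SD²/δ²⌉ per group; its *true* power is then
re-evaluated under the known truth σ = 1.  *Assurance* is the probability,
over the pilot's sampling distribution, that the planned trial attains at
least a stated power floor — available both exactly (chi-square CDF) and by
simulation.

**Binary outcomes.** A single-arm pilot of size n yields Y ~ Bin(n, θ) and
the Wilson score 95% interval for θ̂ = Y/n.  Mean interval width, bias and
coverage are computed exactly by summing over all n+1 outcomes weighted by
the binomial pmf, or by Monte-Carlo replication with the replicate count set
by the rule N = ⌈θ(1−θ)/SE²⌉ for a target standard error (0.001 by default).

The headline quantity on both scales is the **relative precision gain**,
100·(W_n − W_{n+5})/W_n: the percentage reduction in mean CI width when the
pilot grows by five subjects (per group for continuous outcomes, in total
for binary ones).  Once this gain flattens, further pilot subjects buy
little precision.

## Worked example

```python
from pilotsize import (mean_ci_width_closed_form, precision_gain,
                       required_sample_size, assurance)

for total in (20, 40, 70, 80):
    df = total - 2
    w = mean_ci_width_closed_form(df)
    print(f"total={total:3d}  df={df:3d}  mean 95% CI width for SD_p = {w:.4f}")

w70, w80 = mean_ci_width_closed_form(68), mean_ci_width_closed_form(78)
print(f"gain from total 70 -> 80: {precision_gain(w70, w80):.2f}%")
print(f"n per group for delta=0.2, 90% power: {required_sample_size(0.2)}")
print(f"assurance of >=80% power from a 20-subject pilot: {assurance(10, 0.2):.4f}")
```

prints

```
total= 20  df= 18  mean 95% CI width for SD_p = 0.7132
total= 40  df= 38  mean 95% CI width for SD_p = 0.4684
total= 70  df= 68  mean 95% CI width for SD_p = 0.3439
total= 80  df= 78  mean 95% CI width for SD_p = 0.3201
gain from total 70 -> 80: 6.90%
n per group for delta=0.2, 90% power: 526
assurance of >=80% power from a 20-subject pilot: 0.7654
```

Read: a 20-subject pilot estimates the SD with a 95% CI about 0.71 SD units
wide — very imprecise.  Growing the pilot to 70 total more than halves that
width, but past 70 each further five-per-group step narrows the interval by
under 10% (6.90% here), so precision gains flatten.  A definitive trial
detecting δ = 0.2 with 90% power needs 526 per group (1,052 total) when
σ = 1 is known; planned instead from a 20-subject pilot's SD estimate, the
trial reaches 80% true power with probability 0.765.

The full simulation study runs from the command line and writes tidy CSV
tables (one row per grid cell) plus a machine-readable manifest:

```
pilotsize run --seed 1 --outdir results/      # default grids
pilotsize calc samplesize --effect-size 0.2   # single-shot calculators
pilotsize calc inflate --df 18 --confidence 0.8
pilotsize calc wilson --y 0 --n 10
```

A YAML config (`pilotsize run --config study.yaml`) can override any grid,
error rate, effect size, replicate rule or seed; see
`pilotsize.StudyConfig` for the fields and defaults.

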