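# Methods

## Scope and estimands

`pilotsize` studies one question: how the size of an external pilot trial
controls the precision of the two design parameters that drive a definitive
two-parallel-balanced-group superiority RCT — the standard deviation of a
continuous outcome and the event rate of a binary outcome — and what that
imprecision does to the definitive trial's planned size and realised power.

Everything is either a closed form derived from the exact sampling
distribution or a Monte-Carlo experiment against synthetic pilots whose
generating model *is* the model the estimators assume.  There is no external
data.

## Continuous outcomes

**Sampling model.** Each pilot has two arms of n subjects, outcomes i.i.d.
Normal(μ, σ²) with μ = 0 and σ = 1 by default (both estimands are location-
and scale-equivariant, so this is without loss of generality; the tests
assert the equivariance).  Per-arm variances use the unbiased n−1
denominator.  The pooled estimator is SD_p = sqrt((s₁²+s₂²)/2) with
df = 2(n−1); exactly, df·SD_p²/σ² ~ χ²_df.

**df convention.** We use df = 2(n−1), the degrees of freedom of the pooled
variance of two balanced arms.  The df is an explicit argument everywhere,
so any alternative convention is a call-site change, not a code change.

**Derived quantities.**

* Standard error: se(SD_p) = SD_p/sqrt(2·df), the large-sample (delta-method)
  SE of an SD.
* Confidence limits: SD_p·sqrt(df/χ²_{1−a/2,df}) to SD_p·sqrt(df/χ²_{a/2,df}).
  Chi-square quantiles are lower-tail throughout.
* Mean estimator: E[SD_p] = σ·sqrt(2/df)·Γ((df+1)/2)/Γ(df/2), evaluated with
  log-gamma for numerical stability.  Bias is E[SD_p] − σ (signed; the
  estimator underestimates).  This closed form is the oracle for every
  Monte-Carlo mean in the tests.
* Mean CI width: E[SD_p]·(sqrt(df/χ²_{a/2,df}) − sqrt(df/χ²_{1−a/2,df})).
  The Monte-Carlo width replaces E[SD_p] with the replicate mean; the two
  routes are computed side by side in the study tables and tested for
  agreement within Monte-Carlo error.
* Precision gain: 100·(W_{2n} − W_{2(n+5)})/W_{2n} per five subjects added
  to each group.
* Inflation factor: sqrt(df/χ²_{1−c,df}) at one-sided confidence
  c ∈ [0.5, 1).  c = 0.5 is the median-bias correction; c = 0.8 is the
  default illustration.  Levels below 0.5 would *deflate* the estimate and
  are rejected as outside the method's purpose.

## Definitive-trial planning

**Sample size.** n per group = ⌈2(z_{1−α/2} + z_{1−β})²·SD²/δ²⌉, the
two-sample normal-approximation formula with per-group ceiling rounding and
a floor of 2.  With δ = 0.2, σ = 1, α = 0.05 two-sided and 90% power this
gives 526 per group (1,052 total), the benchmark every planning summary is
compared against.  A noncentral-t variant (`use_t=True`) is available — it
iterates the exact t power function and gives slightly larger n — but the
normal approximation is the default because it is the convention the
benchmark is defined under.

**True power.** Φ(δ·sqrt(n/2)/σ − z_{1−α/2}) under the known truth σ.  The
opposite-tail term Φ(−δ·sqrt(n/2)/σ − z_{1−α/2}) is omitted; it is below
10⁻⁴ everywhere in the studied range.  The round-trip invariant
`true_power(required_sample_size(δ, 1, α, P), δ, 1, α) ≥ P` (ceiling never
undershoots) is tested for all grid effect sizes.

**Assurance.** The probability that a plan built from a random pilot reaches
a power floor (80% by default when targeting 90%).  Two routes, which the
tests require to agree within sampling error:

* *Exact*: the plan reaches the floor iff its per-group n reaches the
  smallest n_floor meeting the floor; through the ceiling rule this is
  SD_used² > (n_floor − 1)·δ²/(2(z_{1−α/2}+z_{1−β})²), an event whose
  probability is a chi-square tail of SD_p².
* *Simulation*: the empirical fraction over simulated pilots.

**Degenerate estimates.** SD_p = 0 cannot occur under the continuous model;
if supplied (pathological input), the plan is excluded from summaries with a
logged count rather than mapped to the minimum size, because it signals
upstream misuse rather than a small trial.

**Summaries.** Per (effect size × pilot size × inflation flag): percentiles
{min, 2.5, 25, 50, 75, 97.5, max} — chosen to reconstruct box-and-whisker
summaries — of true power, of the planned definitive total 2n, and of the
grand total including the pilot, plus the assurance at the floor.
Percentiles use numpy's linear interpolation between order statistics.

## Binary outcomes

**Sampling model.** A single analysed arm of size n with Y ~ Bin(n, θ);
θ ranges over 0.10–0.50 in steps of 0.05 (widths are symmetric under
θ ↔ 1−θ, which is tested, so this covers 0.5–0.9 too).

**Wilson score interval.** Centre (θ̂ + z²/2n)/(1 + z²/n), half-width
z·sqrt(θ̂(1−θ̂)/n + z²/4n²)/(1 + z²/n).  The z quantile is full double
precision, not 1.96, so enumeration, simulation and closed forms stay
mutually consistent.  The implementation is cross-checked against
statsmodels' Wilson interval in the tests.  Endpoints are clamped to [0,1]
and snapped to contain θ̂ — both no-ops analytically, guarding only
floating-point residue at y ∈ {0, n}.

**Enumeration first.** For every (θ, n) cell, the mean observed rate, mean
interval width, bias and coverage are pmf-weighted sums over y = 0..n —
exact and deterministic, and the default for the study tables.  Monte-Carlo
mode mirrors a replicate-based study procedure: per-θ replicate count
N = ⌈θ(1−θ)/0.001²⌉ with a floor of 10,000 (250,000 at θ = 0.5).  Every
simulated cell summary is tested against its enumeration twin within four
standard errors, with the SEs themselves computed exactly from enumerated
second moments.

**Coverage convention.** Closed interval: an endpoint exactly equal to θ
counts as covering.  This matters only at discreteness boundaries.

## Synthetic data: what it does and does not emulate

The generator draws exactly the model the estimators assume — independent
normal outcomes with common variance, independent binomial counts — at the
study conditions: per-group sizes 10..80 (step 5) with 10,000 replicates
each for the continuous grid; single-arm sizes 10..200 (step 5) and the
SE-driven replicate rule for the binary grid.  Passing tests therefore
demonstrate the *sampling-theory* consequences of pilot size, not
robustness: no skewness, unequal variances, clustering, dropout or
measurement error is modelled, and a real pilot's SD estimate can be worse
than these distributions suggest, never systematically better.  Pilots are
drawn independently per grid size rather than shared across sizes; only
per-cell summaries are retained (they are sufficient for every downstream
statistic), with raw outcome vectors available behind a debugging flag.

**Seeding.** A single master seed plus the cell identity (kind, n, θ) is
hashed into a `SeedSequence`, giving every grid cell an independent
substream.  Results are bit-reproducible for a fixed seed and independent of
the order in which cells are evaluated.

## Numerical choices and problem sizes

* Simulation is chunked so memory stays bounded (~16M draws per chunk);
  chunking does not change the stream, which is tested.
* The replicate-count rule uses a 10⁻¹² relative tolerance at exact
  ceilings so 0.1·0.9/0.001² yields 90,000, not 90,001, despite binary
  floating point.
* Monte-Carlo tests use fixed seeds and tolerances of 3–4 standard errors,
  with SEs taken from exact moments (Gamma closed form, enumerated second
  moments) rather than estimated ones wherever available.
* Test problem sizes are chosen so each check resolves its claim: 10⁶
  replicates for the bias bound |bias| < 0.005 at total 60 (MC SE ≈ 10⁻⁴),
  10⁵ pilots for assurance (SE ≈ 0.0013 against a 0.76 floor), 10⁴
  replicates per cell for grid-wide oracle-agreement sweeps.
* The "80% of inflated plans are at least as large as the benchmark" claim
  is established exactly per pilot size through the chi-square distribution
  (the probability is ≥ 0.80 at every size, marginally — 0.8005 at the
  smallest), and the simulation is checked against that exact value within
  sampling error; the empirical fraction alone would sit within one SE of
  the 0.80 boundary at any affordable replicate count.

## Known limitations

* Continuous machinery assumes balanced arms and a common variance; no
  Welch/Satterthwaite analogue is provided.
* Binary outcomes stop at estimation precision; no definitive-trial sample
  size formula for proportions is included.
* The normal-approximation power formula, not the exact t, defines "true
  power"; the difference is negligible at the sizes a δ ≤ 0.5 plan produces
  but would matter for very small definitive trials.
* Assurance is conditional on a known true effect size; no prior on δ
  (Bayesian assurance) is modelled.
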