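# Methods

## Abundance estimation

The survey design is two photographic sighting rounds one week apart over
the same transects, treated as closed-population capture–recapture with
photographic identity matching. The Chapman-corrected Lincoln–Petersen
estimator `N̂ = (n1+1)(n2+1)/(r+1) − 1` is nearly unbiased when the expected
number of resights exceeds roughly seven and detection is independent
across dogs and rounds; both conditions hold comfortably at the pooled
counts used here (83 and 103 resights).

Counts are pooled per domain before estimation — one pool over the 25
surveyed city blocks, one over the 15 suburbs — because block-level resight
counts are small enough to make per-block Chapman estimates noticeably
biased and unstable. Per-block aggregation (`counts_from_records`,
`pool_counts`) is available for diagnostics. The city pool covers a random
25% of the 100-block grid and is extrapolated by ×4; the suburbs are a
census and enter unscaled. Full floating-point precision is kept through
all arithmetic; only the final reported total is rounded, half-up
(922 × 4 + 3093.38 = 6781.38 → 6781).

No confidence interval is attached to the abundance estimate by default: a
two-round design cannot separate detection heterogeneity from sampling
noise, so a variance statement would be mostly assumption. The standard
Chapman variance and a normal-approximation CI are available behind
explicit calls (`chapman_variance`, `chapman_ci`) and flagged as an
extension in the CLI (`--with-ci`).

A dogs-per-km-of-route index is computable only when the caller supplies
the total surveyed street length (`route_km`); it is never defaulted,
because route length is a property of the field campaign, not of the
counts.

## Demographic comparison

City-vs-suburb contrasts are unadjusted 2×2 odds ratios, `OR = ad/bc`, with
95% CIs by Woolf's log method, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`. When
any cell is zero the Haldane–Anscombe correction adds 0.5 to every cell and
the result is flagged (`method="woolf_haldane_corrected"`); an empty row or
column leaves the odds undefined and raises. Multivariable (adjusted)
regression is deliberately out of scope: it needs record-level covariate
data, whereas the univariate ORs are fully determined by the published
marginal counts. Records with an unknown level of the variable under test
are excluded listwise for that variable only.

Location concentration within the city is tested by a Pearson
goodness-of-fit χ² of the five named location categories (vacant lot,
street/sidewalk, alley, public park, restaurant/garbage) against a uniform
null, with df = k − 1. The chi-square arithmetic is delegated to
`scipy.stats.chisquare`.

## Population dynamics model

Stocks: puppies/young (< 12 months) and adults. Parameters, with defaults:

| parameter | meaning | unit | default |
|---|---|---|---|
| `Q` | litters per female per year | 1/yr | 1.0 |
| `Np` | pups per litter | dogs | 2.3 |
| `M` | finite annual mortality | 1/yr | 0.23 |
| `fm` | female proportion parameter ("F/M") | – | 0.3125 |
| `du1` | puppy→adult maturation time | yr | 1.0 |
| `K` | carrying capacity | dogs | 16,592 / 24,200 / 55,000 |
| `s` | annual female spay coverage | 1/yr | scenario-specific |

Derived rates: `B = fm·Q·Np`; `A = (B/(B−M))·ln(1+B−M)`;
`D = (M/(B−M))·ln(1+B−M)`, with the analytic limit `A = B, D = M` taken
when `|B − M| < 1e-12`. Density dependence is `kt = 1 − Population/K`,
clamped to [0, 1].

Per step (explicit Euler, default `dt` = 1 year):

```
Female   = Adult·fm          Female.W = Female·s     Female.F = Female − Female.W
Birth.Rate = A·(1 − s)       QS = Female.W/(Population·fm)
BI     = Birth.Rate·(Male + Female.F)·kt
Death1 = Puppy&Young·D·kt + Puppy&Young·QS·Birth.Rate
Death2 = Adult·D·kt + QS·Birth.Rate·Adult
D1     = Puppy&Young/du1
ΔPuppy&Young = BI − Death1 − (D1 − Death1)        ( = BI − D1 )
ΔAdult       = (D1 − Death1) − Death2
```

Three structural choices deserve a note, because they are retained
deliberately rather than "corrected":

1. **The young-stock death flow cancels.** The puppy/young equation
   subtracts `Death1` and then adds it back inside the maturation bracket,
   so young dogs effectively leave the stock only by maturation, and
   `Death1` acts on the adult inflow instead. The two stock equations still
   sum to `ΔPopulation = BI − Death1 − Death2`, the aggregate net-flow
   identity, which is asserted exactly in the tests.
2. **Births are attenuated by (1 − s) twice** — once through the effective
   birth rate `A(1−s)` and once through the breeding pool
   `(Male + Female.F)`. This makes the response to spaying stronger than a
   single-attenuation model.
3. **QS divides by total population, not adults**, slightly diluting the
   spay-linked loss terms.

These are the defining equations of the model this package reproduces; the
scenario-table checks in the acceptance tests only pass under this exact
reading (the year-5 projections agree within a fraction of a percent).
Sterilization is a per-year rate applied to the current female stock — no
persistent spayed-female compartment is carried — and is assumed evenly
distributed over the area. Immigration/emigration, abandonment, rehoming,
seasonality and disease are outside the model.

Numerical choices: annual Euler steps match the model's annual rates and
annual reporting; `dt` is configurable (e.g. 1/12) for sensitivity checks,
and a monthly-step run stays within ~15% of the annual-step 5-year
projection, a discretisation gap the ±10% acceptance tolerance on published
scenario values absorbs at year 5. Stocks are clamped at zero and `kt` at
[0, 1] to prevent sign flips on discrete overshoot. Fold changes are
reported against the 6,781 baseline (1,547 + 5,234) and against the
matched no-intervention run.

## Monte Carlo uncertainty

`Q ~ Normal(1, 0.01)`, `Np ~ Uniform(1, 3.6)`, `M ~ Normal(0.23, 0.01)`;
`fm` and `du1` are fixed. The second Normal parameter is interpreted as the
**standard deviation** (a `sd_is_variance` switch exists): with SD = 0.01
the Q and M draws stay tight around their means and the wide, asymmetric
uncertainty intervals are driven almost entirely by the litter-size
uniform, which matches the shape of the published intervals. Normal draws
are truncated to their valid range by redrawing (practically never
triggered at these spreads). Draws with `B ≤ M` use the analytic limit
branch of the rate transform by default (`b_le_m="resample"` redraws them
instead); under the default distributions `B ≥ 0.31 > M` almost surely.

Each draw's parameters run through the same stepping kernel as the
deterministic model (a single code path, so a zero-spread single-draw
ensemble equals the deterministic trajectory exactly). The central estimate
is the ensemble mean; the 95% UI is the 2.5th–97.5th percentile band
(linear interpolation between order statistics). Fold changes against no
intervention use common random numbers: the baseline ensemble re-uses the
same parameter draws, so the ratio of means is not inflated by independent
sampling noise. Default 10,000 draws; every randomised entry point takes an
explicit seed and is bit-reproducible.

## Synthetic data generator

The generator emulates the world in which the estimator is valid: a closed
population of known size per stratum, each dog detected independently in
each round with fixed probability, round-2 detections of round-1 dogs
flagged as resights. Attribute distributions default to the field survey's
observed proportions (sex 65.3/21.1/13.6; locations 46.2/24.4/24.4/4.2/0.8)
so synthetic records resemble real ones. A `misid_p` parameter lets a true
resight go unrecognised, reproducing the photographic mis-identification
failure mode (it biases the estimator upward; documented in a test, never
asserted as unbiasedness). `replicate_chapman` is a vectorised
binomial-count shortcut for calibration studies (2,000 replicates in
milliseconds) that skips per-dog rosters.

What passing synthetic tests do **not** show about real data: real dogs are
not equally detectable (pack behaviour, activity at survey hour),
detection is not independent across rounds at the same hour and track, and
photographic identity matching has an error rate. The calibration results
certify the estimator under its own assumptions, not the field estimate's
accuracy.

## Known limitations

- The published location χ² statistic cannot be recomputed from published
  marginals alone (underlying N unavailable); the statistic is implemented
  and tested on synthetic counts only.
- The sex-ratio tension: the survey observed a strongly male-skewed adult
  population, while the model fixes the female share at `fm = 0.3125`
  everywhere it appears. The model is reproduced as defined.
- Two-round data cannot support multi-occasion log-linear
  capture–recapture models, heterogeneous-detection corrections, or a
  defensible abundance CI.
- The scenario model is deterministic in structure; all reported
  uncertainty comes from the three parameter distributions.
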