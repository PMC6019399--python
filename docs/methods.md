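# Methods

## The question

A scale circulus spacing index (SCSI) is treated as a fixed, per-fish proxy
for early marine body size. If juveniles are sampled in their first ocean
summer and adults the following year, and adult SCSI sits to the right of
juvenile SCSI, two generating mechanisms can explain the shift:

1. **Knife-edge size-selective mortality** — every fish whose SCSI falls
   below a critical limit dies before adulthood; adults are a left-truncated
   version of the same population.
2. **A second, unsampled juvenile population** — larger fish (for instance,
   earlier migrants) were never available to juvenile sampling but do appear
   in the adult sample; adults are a mixture.

Both raise the adult mean. They differ sharply in every other descriptive
statistic, and that contrast is what this package simulates and tests.

## Generating model

The juvenile population is a finite collection of N i.i.d. Normal(μ, σ)
SCSI values; study defaults μ = 30, σ = 5, N = 10⁶ (SCSI treated as
dimensionless "SCSI units" throughout). Mortality is knife-edge at a
critical limit c: survivors are exactly the values ≥ c (a value equal to
the limit survives — a measure-zero convention fixed for reproducibility).
The limit for a target mortality rate m is the quantile c = μ + σΦ⁻¹(m),
computed at full floating precision. At the four study rates this gives
25.79, 28.73, 31.27, 34.21 (2 dp). Note the second value: published tables
of these limits print 28.74, but Φ⁻¹(0.4) = −0.25335 gives 28.7333, which
rounds to 28.73; we treat the printed 28.74 as a rounding slip and the
validation helper flags any user-supplied limit more than 0.005 from the
implied quantile.

Closed-form moments of the left-truncated normal come from the raw-moment
recursion m_k = (k−1)m_{k−2} + a^{k−1}λ (a the standardised cut, λ the
inverse Mills ratio); mixture moments from central-moment combination.
Both are unit-tested against `scipy.stats.truncnorm` and against a
brute-force Monte-Carlo oracle of 10⁷ draws.

## Replicate engine

Per scenario, each of R replicates draws a juvenile sample of n_j from the
parent population, truncates the population at the critical limit, draws an
adult sample of n_a from the survivors, and computes the descriptive
battery of the adult sample with the juvenile maximum as the exceedance
reference. Each statistic is then summarised at its 50th percentile across
replicates (linear interpolation between order statistics). Study defaults:
R = 10,000; factorial n_j ∈ {50, 200, 1000} × n_a ∈ {50, 200, 600, 1000} ×
m ∈ {0.2, 0.4, 0.6, 0.8}.

Design choices:

* **Fixed vs regenerated population.** Whether the 10⁶ population is built
  once per scenario or redrawn is not determinable from the study
  description; both are provided. The default (`fixed-population`) builds
  it once per scenario seed and samples without replacement each replicate;
  `fresh-draws` samples the parametric distribution directly (inverse-CDF
  for the truncated adult pool), which is statistically indistinguishable
  at N = 10⁶ and faster. The two modes agree in tests.
* **Sampling.** Juvenile and adult samples are independent; sampling within
  a sample is without replacement, implemented by collision-rejection on
  indices (O(n) for n ≪ N rather than the O(N) partial shuffle).
* **Seeding.** A master seed spawns one `SeedSequence` child stream per
  replicate, so results are independent of execution order and safe to
  parallelise; every output records the seed.
* **Mixture experiment.** Adult samples use exact component counts
  round(fraction × n_a) (fractional counts round half away from zero, the
  largest component absorbing any residual); a binomial-composition mode
  exists for sensitivity analysis. The juvenile reference sample comes from
  component 1 only. Its size is not stated in the study design; the default
  sets it equal to n_a (configurable). The exceedance (%) column is the one
  statistic sensitive to this choice.

## Descriptive battery

n, mean, median, min, max, range, SD (n−1 denominator), skewness, excess
kurtosis, and % of values strictly exceeding the reference maximum.
Skewness/kurtosis default to the bias-corrected G1/G2 spreadsheet
convention — G1 = [n/((n−1)(n−2))]Σz³,
G2 = {n(n+1)/[(n−1)(n−2)(n−3)]}Σz⁴ − 3(n−1)²/[(n−2)(n−3)] — consistent
with a normal population scoring 0.00; the uncorrected moment ratios are
available behind a flag. "Kurtosis" always means excess kurtosis. For
n < 4 the shape statistics are reported as undefined (NaN).

## Diagnostics

`diagnose_pair` evaluates the checklist juvenile → adult. The knife-edge
verdict requires the full conjunction — mean up, SD down, range down,
skewness up, kurtosis up, and observed exceedance at or below the 97.5th
percentile of its Monte-Carlo null band — because each is an unconditional
consequence of left truncation; partial agreement is reported as
indeterminate rather than scored probabilistically. The second-population
verdict fires when the mean rose but SD or range rose, or the exceedance
broke the null bound. The null band (`expected_null_exceedance`) simulates
the single-population knife-edge null and returns the median, mean, and
central 95% interval of the exceedance percentage; with no mortality its
mean is the exchangeability value 1/(n_j + 1). Because the knife-edge
verdict embeds a 97.5%-coverage bound, about 2.5% of truly knife-edge
datasets are expected to miss that verdict; the simulated recovery rate at
80% mortality, n = 200, is ≈97%.

A 1-df chi-square goodness-of-fit on the {exceeding, not exceeding} counts
is provided for comparing an observed exceedance against any expected
proportion; expected cells below 5 (below 1) set caveat flags. Published
chi-square values for specific hatchery comparisons are *not* asserted
anywhere: the underlying sample sizes and expected proportions were never
printed, so only the generic operation is supplied.

`project_adult_histogram` pushes a binned juvenile distribution through a
hypothesised knife-edge cut: the cut point is the empirical mortality-rate
quantile with uniform interpolation inside the cut bin (source histograms
are coarse; no finer information exists), mass below it is removed, the cut
bin is kept pro-rata, and surviving mass is rescaled to the requested adult
total. Counts are returned as real numbers so conservation is exact; round
for display only.

## What the synthetic generator does and does not emulate

The generator reproduces the study's idealised world: normal SCSI, a
perfectly fixed index over the life cycle, knife-edge (step-function)
mortality, and representative random sampling. Real data violate most of
these — mortality is at best a steep logistic, scale measurements carry
reading error, circulus deposition varies with temperature and growth rate,
and juvenile sampling can be size-biased, which is the package's own
second-population hypothesis. Passing tests therefore validate the
*logic* of the inference framework — which descriptive-statistic patterns
each mechanism can and cannot produce — not any claim about a particular
salmon stock.

## Known discrepancies in the published reference tables

The published knife-edge table's Median/SD/Max/Kurtosis/Skew columns are
not consistent with knife-edge truncation of the stated Normal(30, 5)
population: 20% truncation implies an adult median ≈ 31.3 and SD ≈ 3.8,
where the table prints 30.5 and 2.6 (the printed SDs ≈ 2.6/2.0/1.6/1.2 are
consistent with a substantially narrower generating distribution). The
engine implements the stated generating model, and these columns are
checked instead through properties that do not depend on the ambiguity:
the adult-sample minimum (pinned at the truncation boundary: 26.0 at 20%
mortality), the directional trends of every statistic with mortality rate,
agreement of large-sample summaries with the closed-form truncated normal,
and the exceedance bounds (≤1% with 1,000 juveniles, ≤4.5% with 200). The
mixture table, by contrast, reproduces essentially cell for cell
(30.5/5.2 at 90:10 with Normal(35,5), n = 200; 32.5 at 50:50; 36.0/7.0 at
40:60 with Normal(40,5), n = 50); its % column alone depends on the
unstated juvenile reference sample size.

## Problem sizes and tolerances

The acceptance script and the end-to-end tests run the quoted scenarios at
the full R = 10,000; property-level trend checks use R = 2,000 and the
large-sample oracle comparison uses n_a = 10⁴ with R = 200, sizes at which
the Monte-Carlo standard error of a summarised statistic is an order of
magnitude below the tolerance being asserted (summaries quoted to one
decimal are asserted to ±0.05; bound claims are asserted as bounds).
Mass-conservation and worked-example checks on the histogram projection
are exact to floating precision.
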