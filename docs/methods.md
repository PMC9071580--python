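# Methods

## Estimation model

### Drake path (partial plating)

The unit of estimation is a table of mutant colony counts from `n`
replicate cultures, each of `N` cells at saturation, of which a fraction
`s` was exposed to selection. The chain is:

1. **Central tendency.** C&#770; = exp(mean of ln c over nonzero c) ×
   (#nonzero/#total); zero when all counts are zero. The geometric mean
   damps the jackpot counts that dominate Luria–Delbrück-distributed
   data, while the nonzero-proportion factor keeps the statistic usable
   when more than half the replicates are zero (where a median
   collapses).
2. **Frequency.** f = C&#770;/(N·s), the mutant frequency among cells
   actually exposed to selection.
3. **Rate.** μ solves μ·ln(Nμ) = f. h(μ) = μ·ln(Nμ) − f is strictly
   increasing on [e/N, ∞) and h(f) ≥ 0 whenever f ≥ e/N, so the root is
   bracketed by [e/N, f] and found by Brent's method (residual tolerance
   1e-12 relative; cross-checked in tests against plain bisection and
   the closed form μ = exp(W(Nf))/N via the Lambert W function).
   Frequencies in (0, e/N) are *outside the approximation's domain*: the
   relation has no root with ln(Nμ) ≥ 1 there, and the library raises
   rather than extrapolating. f ≤ 0 returns a flagged zero.
4. **Bootstrap.** Percentile interval over B (default 10,000) resamples
   of the replicate counts, resample size = original size. All-zero
   resamples contribute μ = 0; resamples whose frequency falls below
   e/N contribute the domain edge e/N (the closest admissible value —
   aborting a resample would bias the interval upward). The interval is
   widened, if needed, to include the point estimate (discrete resamples
   can narrowly miss it).
5. **Detection correction.** A LOH-generating division of a +/− cell
   yields a selectable −/− daughter only about half the time, so rates
   and both CI bounds are doubled, after the interval is built
   (multiplication commutes with percentiles). Densities per 10 kb use
   *uncorrected* rates; the genome-wide extrapolation
   Σ(corrected rates)/coverage uses corrected ones — matching the order
   of operations in the source analyses the pipeline reproduces.
6. **All-zero tables** return a flagged zero with a separate
   rule-of-three-style bound 3/(n·N·s), clearly marked as an extension,
   never mixed into the rate itself.

Known bias: under heavy plating dilution the counts are strongly
zero-inflated and C&#770; converges toward the (jackpot-dominated)
arithmetic mean of the sampled distribution rather than its median-like
centre. Measured on simulated panels (30 replicates, N = 2.2e7,
s = 1/200, detection 0.5), the median corrected estimate overshoots a
true 1e-6 per division by a factor ≈1.8, falling to ≈1.1 by 1e-5 and
above. The bias is a property of the estimator, not the simulator: it
is *larger* (≈2.1×) under the exact Luria–Delbrück sampler. Interval
coverage inherits this: the percentile bootstrap covers a true 1e-5 rate
in ≈88% of tables at nominal 95% (measured over 600 tables), the
shortfall coming from the median bias plus the usual n = 30 percentile
undercoverage.

### Maximum-likelihood path (whole plating)

When entire cultures are plated (s = 1), counts follow the
Luria–Delbrück distribution with m expected mutations per culture,
computed by the Ma–Sandri–Sarkar recursion (equivalently a compound
Poisson with clone-size law P(j) = 1/(j(j+1))). m&#770; maximises the
count log likelihood via golden-section search on ln m (tolerance 1e-6)
inside a bracket found by doubling from a moment-based guess; the 95% CI
is the profile-likelihood set 2[ℓ(m&#770;) − ℓ(m)] ≤ 3.841 (χ²₁), and
rates are m/N&#8348;. Counts above a cap `rmax` (default: largest count,
at most 1,000) enter the likelihood as a censored tail of probability
1 − Σp&#7523; — whole-plated 10⁷-cell cultures produce occasional
jackpots far beyond any feasible pmf cache, and censoring is the
standard ML treatment. All-zero tables use the closed form: the
likelihood is e^(−nm), so the 95% upper bound is 1.9207/n.

The LD tail is heavy (p&#7523; ~ m/r², tail mass beyond rmax ≈
m/(rmax+1)), which is why censoring, not truncation depth, is the right
tool; the tests assert this inverse-square law directly.

## Forward simulator

`SimConfig` defaults *are* the emulated design: inoculum 100 cells,
final 2.2e7 cells, detection probability 0.5 per event, plating fraction
1/200, 30 replicates. Growth models:

* `synchronous` (default): g = ceil(log2(N/n0)) synchronous doublings
  with the population interpolated geometrically so total divisions sum
  exactly to N − n0; events per generation are Poisson(μ × divisions),
  thinned by the detection probability, and an event at generation i
  founds a clone of 2^(g−i) cells (capped at N). Transparent and fast;
  because clone sizes are exact powers of two its count distribution
  matches the LD law in p₀, p₁ and mean event count but not in higher
  terms (e.g. the leading coefficient of p₂ is m/4 vs the LD m/3).
* `lea_coulson`: the exact compound-Poisson form (Poisson(m) events,
  clone sizes floor(1/U)), used where distributional exactness matters;
  it doubles as an independent cross-check of the pmf recursion
  (chi-square agreement over 1e5 cultures is a standing test).

Plating is binomial thinning. The positional rate model used for panel
simulations is
rate = d × base × (1 + A_tel·e^(−d_tel/s_tel)) × (1 − A_cen·e^(−d_cen/s_cen));
amplitudes ≥ 0, A_cen ≤ 1. Panel defaults in the tests and acceptance
script: base 1e-9/bp for the 40-kb variable-position panel (per-segment
rates ≈ 4e-5, mutant frequencies within the observed assay range) and
1e-10/bp for the 32-segment mid-arm panel (rates 6e-6 to 7e-5);
amplification 3 toward telomeres and suppression 0.5 toward centromeres
with 100-kb length scales, mirroring the qualitative pattern the
statistics are meant to detect.

The simulator treats N as fixed per configuration (no culture-to-culture
variation), assumes no fitness cost of LOH during growth, and applies
detectability per event, not per cell. These simplifications mean
passing recovery tests demonstrate correctness of the estimation chain
under the fluctuation-assay model, not robustness to real-world
violations of it (plating-efficiency drift, N variation, clone
interference).

### Starvation generator

Viability decays exponentially; the default hazard 0.02766/day is
calibrated so that viability at day 7 is 0.824 (the first published
time-course viability point the generator is asked to emulate). Among
survivors the mutant frequency rises linearly at λ per 2-hour unit
(12 units/day) on top of a baseline 1e-4 carried over from prior growth
(within the observed frequency range; it only shifts the regression
intercept). Sampling is Poisson at both platings; 30 wells are pooled
per sampling for the main design (3 for controls), nonselective platings
aim for tens of countable colonies, selective platings use a 1/20
fraction. The model deliberately has no mutant survival advantage and no
growth during starvation — the control-stability statistics exist to
test exactly those assumptions on data.

## Pattern statistics

Arm-length correlation is Pearson's r of per-10 kb density against the
*rank* of arm length (midranks on ties); distance correlations are
Spearman's r_s. The element/transcription regression z-scores all
predictors, then does OLS with stepwise AIC selection in both directions
starting from the full model; exactly collinear pairs drop the later
column with a warning. The direction/criterion ("both", AIC) is a
documented choice — the procedure the analysis names does not pin down
the score. The arm × strain comparison is a two-factor ANOVA without
interaction on log10 rates (rates span orders of magnitude; the raw
scale is available via `log_response=False`), with Tukey HSD contrasts
and the contrasts against a chosen reference strain (the homozygote)
pulled out. P-values are reported uncorrected for multiplicity.

## Starvation analysis

Frequencies are ratios of two independent platings rescaled by their
sampled fractions; the day-3 conditioning sample is the first regression
point (t = 36 two-hour units). The regression is unweighted OLS with an
intercept. The growing/starving comparison assumes one division ≈ one
2-hour unit, sums per-division rates and per-2 h slopes over the common
segment panel (default exclusions: the rDNA-bearing 12R and 13R), floors
negative slopes at zero with a warning, and reports a non-finite ratio
when the denominator vanishes.

## Numerical and design choices

* Coordinates are 1-based inclusive; BED input is converted on read.
  Element and gene membership in a segment is by interval midpoint,
  closed on both ends, so splitting a segment conserves counts exactly.
* The packaged genome layout is an approximate S. cerevisiae table
  (16 chromosomes, lengths and centromere midpoints); exact coordinates
  can be swapped in as a TSV.
* Element densities are computed over the between-marker interval (not
  centromere-to-URA3); this is the reading adopted throughout and the
  natural sensitivity axis if revisited.
* All randomness flows from `numpy.random.Generator` objects; identical
  configuration + seed reproduces byte-identical outputs, including the
  bootstrap.
* Problem sizes in the standing checks — 200 simulated panels per
  recovery point, 200 tables × B = 1,000 for coverage, 100 seeds for
  sign recovery, 50 for the starvation ratio — were chosen to keep each
  check's Monte-Carlo error well inside the property being asserted
  while the whole suite stays fast.

## Known limitations

* The Drake-path estimator's small-count bias (above) is structural;
  below mutant frequencies of a few per plate, treat point estimates as
  upper-biased by up to ~2× and prefer the ML path where whole-culture
  plating is available.
* The Drake relation is undefined below f = e/N; segments with very low
  rates need larger plated fractions, not a different solver.
* The stepwise regression inherits the usual post-selection inference
  caveats: retained-predictor p-values are not selection-adjusted.
* No modelling of return-to-growth recombination, phenotypic lag, or
  post-plating growth.
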