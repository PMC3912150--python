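# Methods

## Scope and model

`fireregime` implements a landscape-scale analysis of fire regimes in
montane conifer forests (ponderosa/Jeffrey pine and mixed conifer), built
around three quantities:

1. **Fire rotation** at a chosen severity: the time for cumulative burned
   area at that severity to equal the region area, `rotation = period /
   fraction_burned`.  Burned areas are summed, not unioned — the rotation
   concerns "an area equal to the area of interest", so reburned ground
   counts again and the burned fraction may exceed 1.  Severity is
   classified from basal-area mortality of woody species: low [0, 0.20),
   moderate [0.20, 0.70], high (0.70, 1].  The band edges sit with the
   lower-intensity class except that "high" is strictly above 70%; this
   convention is stated once in `severity.py` and tested explicitly.
2. **Stand-origin distributions** from forest-inventory plots: stand age =
   cover-weighted mean ring count of dominant/codominant cores + 8 yr to
   breast height; origin year = measurement year − stand age; origins
   binned in half-open 40-yr calendar classes anchored so 1810, 1850,
   1930, 1970 are left edges.  Origin-year binning (rather than age
   binning) keeps windows comparable across measurement years.
3. **Regime tests**: a goodness-of-fit of the suppression-era (1930–2009)
   origin classes against a *no-exclusion counterfactual* (the 1810–1889
   classes shifted forward 120 yr and rescaled to the observed total), a
   goodness-of-fit against a *low/moderate-severity null* (12.5% of stands
   in each 40-yr class covering ages 0–319 at the exclusion onset), and a
   Yates-corrected two-proportion chi-square for 2×2 comparisons such as
   pine vs non-pine establishment.  The establishment-rate change factor
   is the ratio of mean per-bin counts, 1810–1889 over 1930–2009.

## Plot filters and special cases

* Only protected (wilderness/roadless/park), land-class-qualifying plots
  enter; exclusions are tallied by first failing reason.
* Split-age plots are excluded.  FIA splits plots whose subplot ages
  differ by ≥1 yr (both ages ≤100), ≥2 yr (both 100–199) or ≥15 yr (both
  ≥200).  Pairs straddling categories use the younger member's threshold —
  the conservative choice (more exclusions); age exactly 100 uses the
  1-yr threshold.  Both choices are documented here because the category
  boundaries are ambiguous in the underlying protocol descriptions.
* Non-stocked plots (no live tree that can be aged non-destructively) are
  dated by their recorded fire-disturbance year; with no code they go to
  the most recent bin, flagged.
* The newest bin is right-censored: fire after the sample date is
  invisible.  `correct_recent_bin` inflates it by `40/(40 − m)` with
  `m = horizon − midpoint(sampling window)` under uniform sampling, e.g.
  40/36 for a 2001–2009 window read at 2009.  Published region-specific
  factors (40/34, 40/32.5) do not all equal the midpoint value, so a
  verbatim factor override is accepted and recorded in metadata.
* Plots originating before the configured grid start are kept in an
  open-ended "older" count, reported separately.
* Non-fire disturbance codes are retained and flagged but never reassign
  origins.

## Proportional tree-age noise

Within-plot tree-age scatter is summarised as the SD of
`(tree age − stand age)/stand age`, pooled over all cores.  Because each
plot's stand age is the mean of its own k cores, deviations from it carry
only (k−1)/k of the noise variance; the pooled estimator therefore divides
by (total trees − plots), which is unbiased for the generative
proportional SD under equal cover weights.  A divide-by-n convention
would report ~0.125 for true noise 0.14 at k = 5; the chosen convention
recovers 0.14 (tested closed-loop).  With a single two-core plot at ages
{90, 110} around stand age 100 the estimate is √0.02 ≈ 0.141.

## Chi-square details

* Goodness of fit: Σ(O−E)²/E, df = bins − 1, upper-tail p from the χ²
  distribution.  Adjacent bins with expected < 5 are pooled left-to-right
  (recorded in the result); pooling can be disabled to mirror published
  analyses that do not mention it.
* Two proportions: pooled-variance statistic with Yates continuity
  correction by default, `(|p₁−p₂| − ½(1/n₁+1/n₂))²` clamped at zero over
  `p̄(1−p̄)(1/n₁+1/n₂)`, df = 1.  The uncorrected variant equals the
  Pearson 2×2 statistic algebraically and is cross-checked numerically
  against an independent contingency-table implementation.
* Calibration: the goodness-of-fit test and the *uncorrected*
  two-proportion test hold their nominal 5% size under simulated nulls
  (multinomial draws; paired binomials at n = 2000).  The Yates-corrected
  test is conservative by construction — that is its purpose — so size
  calibration is asserted for the uncorrected form.
* **Known property of the no-exclusion test**: the counterfactual expected
  counts are estimated from the historical bins of the same inventory.  A
  goodness of fit that treats them as known over-rejects by roughly
  (1 + n_recent/n_historical) under a true null; with comparable era
  totals the realised size is ~0.2 at nominal 0.05.  The pipeline itself
  is unbiased — against analytic stationary bin proportions the identical
  simulate→sample→process→test loop rejects at 0.053 — so the
  anticonservatism is a property of the published test construction, and
  is pinned in the test suite rather than silently "fixed".  Relatedly,
  because the counterfactual is rescaled to the observed suppression-era
  total, the 2-bin comparison tests the *shape* of the era, not its level:
  a uniform drop in establishment appears in the establishment-change
  factor (which is tested for monotonicity in the exclusion multiplier),
  not in this χ².
* Counts printed only as rounded percentages are reconstructed with
  `counts_from_percent`, which warns and lists all candidates when the
  inversion is ambiguous.

## Synthetic landscape generator

The simulator provides ground truth for every inference stage.  A region
is a set of 1-ha cells holding stand-origin years; initial ages are drawn
from the stationary exponential distribution of the high-severity
rotation.  Each year, each configured severity channel burns an expected
area `region/rotation` (scaled by the exclusion multiplier from the onset
year), realised as a Poisson number of patches with truncated power-law
sizes (density ∝ s^−α on [s_min, s_max], default α = 2 on [1, 5000] ha —
heavy-tailed, as observed for fire patch mosaics; the exact law is a
modelling choice) placed on uniformly random cells.  High-severity patches
reset cell origins; moderate-severity patches reset each covered cell with
probability equal to the patch's drawn mortality fraction (a literal
reading of basal-area mortality as dominance-shift probability);
low-severity patches reset nothing.  Patch placement is spatially
uncorrelated between years: the analysis consumes only marginal age
distributions and burned fractions, which this reproduces; patch size
affects only the variance of those marginals.

Plot sampling draws one plot per D ha (default 2,400) at random cells,
measurement years uniform over the inventory window.  Ring counts are
`stand_age·(1 + N(0, σ)) − 8`, truncated at zero and rounded, so the
pipeline's +8 recovers cell age in expectation; σ defaults to 0.14, the
value observed in real inventories.  Plots whose stand is younger than
the non-stocked lag (default 5 yr) are emitted non-stocked with the fire
year as disturbance code, optionally dropped at a configurable missing-
code probability (with a Pacific-style "<6 years" coding mode).  Split
plots are drawn with a configurable probability (a nuisance parameter
with no published generative model; it exists to exercise the exclusion
filter) and report a second subplot age from the nearest cell with a
different origin.

What the generator does *not* emulate: spatial contagion and
autocorrelation of patches, fire-weather and fuel dynamics, species
demography, climate-driven regeneration failure, and survey or
record-keeping errors beyond the modelled noise.  Passing closed-loop
tests therefore demonstrates that the pipeline recovers the parameters of
a stationary, spatially unstructured regime; it does not validate the
ecological realism of any particular published reconstruction.

## Numerical and statistical choices in the validation suite

* Problem sizes: rotation recovery uses 100,000 ha × 200 yr with patches
  on [1, 100] ha, which keeps the compound-Poisson noise of the burned
  fraction near 2% so a 10% tolerance is a multi-sigma check; the
  exclusion-signature run uses 4.8 M ha (2,000 plots at 1/2,400 ha) at a
  1,200-yr rotation.
* Age-law bounds: cells burn in patches, so cell indicators are
  cluster-correlated and iid binomial bounds would reject a correct
  simulator roughly half the time.  The 99% bounds are widened by the
  compound-Poisson design effect E[S²]/(E[S](1−p)) computed analytically
  from the configured patch-size law; the widened bound matches the
  empirical replicate variance within a few percent.
* Expected value of the exclusion signature: in any stationary regime the
  1810–1889 bins are depleted by reburn between origin and measurement,
  so with a multiplier of 0.25 the expected factor is ≈3.7–3.8 at a
  1,200-yr rotation, not 4.0; its single-draw SD at 2,000 plots is ≈0.8.
  The accepted band in the tests reflects this.
* Determinism: every stochastic path takes a `numpy.random.Generator` or
  a seed; fixture generation with equal seeds is byte-identical.
* Degenerate inputs: zero burned fraction yields a flagged infinite
  rotation (not an error); an all-success 2×2 returns statistic 0;
  both-zero historical bins raise a degenerate-null error; empty bins
  render as zero-height bars.

## Limitations

* The rotation arithmetic is shared, but published rotations rest on
  upstream reconstructions (land-office surveys, air photos, maps) that
  are out of scope; regional headline statistics from the real inventory
  database are likewise not reproducible without that database.
* The "mean stand age at 1930" summary rewinds retained plots
  (age = 1930 − origin, dropping post-1930 origins); the rewind rule is a
  documented choice, as the published tables do not state one.
* The exact bin sets behind published per-region χ² values are not fully
  stated; `analyze` records its windows in the results JSON.
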