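# fireregime

Tools for asking a landscape-scale question about montane conifer
forests: were they shaped by **low/moderate-severity fire** (frequent
surface fire, stable old stands, low age-class diversity) or by
**mixed-severity fire** (low, moderate *and* stand-replacing high-severity
patches, producing diverse stand ages)?  And how did a century of fire
exclusion change them?

The package is aimed at fire ecologists and forest biometricians working
with forest-inventory plot tables (FIA-style: stand ages, subplot ages,
tree cores, disturbance codes) and with burn records (dated patches with
basal-area mortality).  It provides:

* **Severity & rotation** (`fireregime.severity`) — classify severity
  from basal-area mortality (low [0, 0.20), moderate [0.20, 0.70], high
  (0.70, 1]) and estimate fire rotations
  `R = period / fraction_burned`, where burned areas are summed so
  reburns count again.  A stationarity-based estimator
  `rotation_from_age_cdf` inverts `P(age < t) = 1 − exp(−t/R)`.
* **Stand-age pipeline** (`fireregime.standage`) — stand age as the
  cover-weighted mean ring count of dominant/codominant cores + 8 yr to
  breast height; protected-lands and split-age filters (1/2/15-yr FIA
  split thresholds); half-open 40-yr origin classes anchored at
  …1810, 1850, …, 1930, 1970…; non-stocked plots dated by fire year; the
  `40/(40 − m)` right-censoring correction for the newest bin.
* **Regime inference** (`fireregime.inference`) — the no-exclusion
  counterfactual (1810–1889 origin classes shifted +120 yr, rescaled),
  the uniform low/moderate-severity null (12.5% per 40-yr class over ages
  0–319 at exclusion onset), χ² goodness-of-fit with small-bin pooling,
  the Yates-corrected two-proportion χ², and the establishment-rate
  change factor (pre-exclusion vs suppression-era mean bin counts).
* **Synthetic landscapes** (`fireregime.simulate`) — a cell-based fire
  simulator (stationary exponential ages, truncated power-law patches,
  configurable exclusion onset and multiplier) that emits burn records
  and FIA-like plot/tree tables, giving ground truth for every stage.
* **CLI** (`fireregime`) — `simulate`, `process`, `analyze`, `report`,
  `verify`, all reading/writing delimited text + JSON with provenance.

## Worked example

Simulate a 2.4 M ha region with a 400-yr high-severity rotation whose
burn rate drops to 30% of its historical value in 1930, sample 1,000
inventory plots (2001–2009), and run the full analysis:

```yaml
# config.yaml
seed: 20260922
regime:
  region_area_ha: 2400000
  high_rotation_years: 400
  patch_max_ha: 500
  exclusion_start_year: 1930
  exclusion_multiplier: 0.3
  span: [1780, 2009]
design:
  plot_density_ha: 2400
  measurement_window: [2001, 2009]
  split_prob: 0.1
  unprotected_prob: 0.05
pipeline:
  region: demo
  start: 1530
  stop: 2010
  correction: {sampling_window: [2001, 2009], horizon: 2009}
analysis:
  alpha: 0.05
```

```sh
fireregime simulate --config config.yaml --out sim
fireregime process  --plots sim/plots.csv --trees sim/trees.csv \
                    --config config.yaml --out proc
# -> retained 872 of 1000 plots (excluded: {'unprotected': 48, 'land_class': 0, 'split': 80})
fireregime analyze  --dist proc/distribution.csv --meta proc/distribution_meta.json \
                    --processed proc/processed_plots.csv \
                    --config config.yaml --out results.json
# -> no-exclusion chi2=0.62 p=0.431
fireregime report   --results results.json --dist proc/distribution.csv \
                    --meta proc/distribution_meta.json --out rep
# -> region  n_plots  mean_stand_age_now  mean_stand_age_1930  chi_square  p_value  establishment_change_factor
# ->   demo      872          458.198394           408.206804    0.620326 0.430926                     2.612903
fireregime verify   --burn-events sim/burn_events.csv --burn-region sim/burn_region.json \
                    --ground-truth sim/ground_truth.json
# -> high-severity rotation over pre-exclusion window (to 1930): estimated 401.0 yr,
#    true 400.0 yr, relative error 0.002
```

Reading the numbers: the rotation estimated from the emitted burn record
(401 yr) recovers the configured 400 yr.  The establishment-change
factor 2.61 is the exclusion signature — the configured 1/0.3 ≈ 3.3 rate
drop, damped by reburn depletion of the pre-1890 origin classes (old
stands that burned again are no longer counted at their first origin).
The low/moderate-severity null is rejected (χ² = 22.1, df = 7,
p ≈ 0.002 in `results.json`): origin classes are far from the even
old-age spread that a regime without stand-replacing fire would leave,
i.e. this landscape looks mixed-severity.  The no-exclusion χ² of 0.62
(p = 0.43) is *expected* here: that comparison is rescaled to the
observed suppression-era total, so it tests the shape of the era, not
its level — the level change is what the establishment factor measures
(see `docs/methods.md`).

The figure written by `report` shows observed origin classes (black)
against the no-exclusion expectation (grey), the same paired-histogram
layout used for regional inventory analyses; the data behind it are
always written as `age_distribution.tsv`.

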