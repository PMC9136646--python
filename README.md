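# heatsense

Indoor heat-exposure analysis from smart-thermostat telemetry.

During declared heat waves, public-health warning systems rely on outdoor
meteorology, yet people experience heat mostly indoors. Fleets of connected
thermostats report indoor temperature, air-conditioning activity and
motion-sensor occupancy every five minutes — a scalable way to find the
dwellings that actually overheat. `heatsense` is a tested pipeline for that
analysis, built around the 2018 Quebec summer (June 1 – August 31, with
official heat waves June 30 – July 5 in the greater Montréal and Outaouais
health regions and August 4 in Outaouais):

- **Ingestion** of three CSV inputs: 5-minute telemetry (indoor temperature,
  cooling stage, HVAC mode, motion), house metadata, and hourly
  weather-station observations in an Environment-Canada-style dialect, with
  row-level validation and full rejection accounting.
- **QC and labeling** per house-day: air-conditioned iff a nonzero cooling
  stage was observed *and* "cool" was recorded as the HVAC mode; non-AC iff
  neither; ambiguous days excluded. Unoccupied (no motion) and incomplete
  (< 80 % of samples or a missing hour bin) days are removed; houses map to
  their nearest weather station, stations need ≥ 30 houses, and only regions
  with a declared heat wave are analyzed.
- **Statistics** on pooled house-day daily means: one-tailed Welch *t* tests
  (unequal variances, Welch–Satterthwaite df, 99 % CI of the difference)
  comparing AC vs non-AC houses on heat-wave and other days and heat-wave vs
  other days within non-AC houses; per-date counts and mean durations of
  hours at or above the 26 °C ASHRAE 55 safe-indoor bound; and an
  hour-by-day heat map with the hottest contiguous window.
- **A calibrated synthetic cohort generator** (the real donated-thermostat
  corpus is access-restricted): group/day-type mean + house random effect +
  late-afternoon sinusoidal diurnal cycle + sensor noise, calibrated so the
  pipeline recovers mean differences of −1.320 / −0.500 / +0.906 °C, group
  means of 22.3 and 23.7 °C, and a 4-hour mean exceedance above 26 °C on
  heat-wave days. See `docs/methods.md` for the model and its limits.

## Worked example

```sh
heatsense run --config configs/pc2018.toml --out results/pc2018 --seed 42
```

generates the calibrated 100 AC + 100 non-AC cohort, runs the full
pipeline, writes `table1.csv`, `fig2_counts.csv`, `fig3_durations.csv`,
`fig4_heatmap.csv`, `qc_report.csv` and `manifest.json` under
`results/pc2018`, and prints:

```
heatsense run (v0.1.0, config d08e230683e0)
  houses: 200 in metadata -> 200 analysed; house-days: 18400 -> 15649
  AC/HW vs NONAC/HW: diff -1.261 degC (means 22.405 vs 23.666, n=548/536, t=-26.33, df=1081, one-tailed p=8.71e-119, 99% CI [-1.385, -1.137])
  AC/NHW vs NONAC/NHW: diff -0.451 degC (means 22.333 vs 22.784, n=7312/7253, t=-34.33, df=14539, one-tailed p=1.19e-248, 99% CI [-0.484, -0.417])
  NONAC/HW vs NONAC/NHW: diff +0.882 degC (means 23.666 vs 22.784, n=536/7253, t=24.92, df=620, one-tailed p=8.36e-96, 99% CI [0.790, 0.973])
  mean time at or above 26 degC on heat-wave days: 3.53 h over 536 non-AC house-days
  hottest indoor hours on heat-wave days: 15:00-19:00
```

Reading the output: of 18 400 simulated house-days, 15 649 survive QC
(occupancy, completeness, unambiguous labels). On heat-wave days,
air-conditioned houses run 1.26 °C cooler than non-AC houses (pooled daily
means, one-tailed Welch p ≪ 0.001); the gap shrinks to 0.45 °C on ordinary
days, and non-AC houses run 0.88 °C hotter during the heat wave than
outside it — each within sampling error of the generator's calibration
(−1.320, −0.500, +0.906). Non-AC houses spend on average ~3.5 h/day at or
above 26 °C on heat-wave days (the calibrated profile crosses 26 °C for
4 h; dwelling heterogeneity of SD 0.8 °C pulls the cohort mean slightly
below that), peaking in the late afternoon.

`heatsense simulate --out <dir> [--scenario file.toml] [--seed N]` writes
just the synthetic input files; `heatsense report <manifest.json>` reprints
a run summary. `heatsense.plots.render_figures(out_dir)` renders PNGs of
the exceedance and heat-map outputs if matplotlib is available.

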