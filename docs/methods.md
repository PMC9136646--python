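# Methods

## Problem and scope

`heatsense` quantifies indoor heat exposure from smart-thermostat telemetry
during declared heat-wave events. The observational setting it models is the
2018 Quebec summer (June 1 – August 31): dwellings with connected thermostats
report indoor temperature, compressor cooling-stage status, HVAC mode and
motion-sensor activation every 5 minutes; official heat waves are declared
per health region (June 30 – July 5 for Montréal, Laval, Montérégie and
Outaouais; additionally August 4 for Outaouais); and the public-health
question is how much hotter non-air-conditioned dwellings run, and for how
long they sit at or above the 26 °C ASHRAE 55 safe-indoor-temperature bound.

Because the real thermostat corpus is access-restricted, the package pairs
the analysis pipeline with a calibrated synthetic cohort generator. The
generator is first-class, tested code: it defines the statistical conditions
under which the pipeline's recovery properties are verified.

## Analysis pipeline

The unit of analysis is the **house-day**. For each house and calendar date
(midnight-to-midnight local standard time):

1. **Aggregation.** Samples are averaged into 24 half-open hour bins
   [h, h+1); the daily mean is the mean of the non-missing hourly means.
2. **Completeness.** A house-day is complete iff ≥ 80 % of the 288 expected
   5-minute samples are present *and* all 24 hour bins are represented. The
   80 %/all-bins rule is this package's choice; the source study states only
   that incomplete data were removed.
3. **Occupancy.** Occupied iff any sample that day has motion. No dwell-time
   minimum is imposed.
4. **AC labeling.** AC iff a nonzero cooling stage (1–4) was observed *and*
   "cool" appears as the HVAC mode, either at any point in the day's
   telemetry or as the configured metadata mode; non-AC iff the stage was 0
   all day *and* "cool" appears in neither source. The unmatched middle
   cases (e.g. nonzero stage but "cool" never recorded) are labeled
   INDETERMINATE and excluded, rather than force-assigned, to avoid
   contaminating either group. Reading the mode disjunctively from both
   sources is an interpretation; the underlying description is ambiguous
   about which source was used.
5. **Station mapping.** Each house maps to a weather station: a pre-assigned
   station id wins; otherwise the haversine-nearest station (ties to the
   lexicographically smallest id); otherwise a city → station lookup.
   Station groups with fewer than 30 distinct houses are dropped, and
   house-days outside regions with a declared heat wave are dropped.
6. **Comparisons.** Pooled daily means are compared with one-tailed Welch
   t tests (unequal variances, Welch–Satterthwaite df): AC vs non-AC on
   heat-wave dates and on other dates (alternative: AC cooler), and
   heat-wave vs other dates within non-AC (alternative: heat-wave hotter).
   These directions are the only ones consistent with the phenomenon being
   measured. Each row reports the two-sided 99 % CI of the mean difference.
   House-days are pooled with no within-house correlation adjustment, so
   p-values are anti-conservative with respect to dwelling-level clustering;
   this mirrors the design being reproduced and is a known limitation.
7. **Exceedance.** For the season-level non-AC subset (houses in calendar
   regions with zero AC-labeled days and at least one occupied heat-wave
   day), each house-day's exceedance duration is the count of hour bins
   with mean ≥ 26 °C ("equal to or greater"). Per date the pipeline reports
   the number of houses with positive duration and the mean duration over
   all contributing houses, zeros included. Computing exceedance on hourly
   means (not raw 5-minute samples) matches the whole-hour resolution of
   the reported durations.
8. **Heat map / hottest window.** Mean indoor temperature per (hour,
   heat-wave date) averaged over houses; the hottest window is the
   contiguous run of hours within 0.2 °C of the maximum hour, which on the
   calibrated cohort is 15:00–19:00.

## Synthetic cohort model

Indoor temperature for house *i* on date *d* at time-of-day *t*:

    T_i(d, t) = mu(g_i, daytype(d, region_i)) + b_i
                + A(g_i, daytype) * cos(2*pi*(t - 17)/24) + eps,

with group g ∈ {AC, non-AC}, day type ∈ {heat-wave, other} from the
region's calendar, house effect b_i ~ N(0, 0.8 °C), and white noise
eps ~ N(0, 0.3 °C) per sample. AC houses emit mode "cool" and duty-cycle
their cooling stage through the hot half of the day; non-AC houses emit
stage 0 and mode heat/off.

Calibration (scenario **PC-2018**, the defaults of `ScenarioConfig`):

| parameter | value | why |
|---|---|---|
| mu(AC, other) / mu(AC, HW) | 22.300 / 22.386 °C | unique solution to the target mean differences −1.320, −0.500, +0.906 °C together with the rounded group means 22.3/22.4/22.8/23.7 |
| mu(non-AC, other) / mu(non-AC, HW) | 22.800 / 23.706 °C | same joint solution |
| A(non-AC, HW) | 2.656 °C | puts the 26 °C crossing so that exactly the four hour bins 15–18 exceed the threshold, with ≥ 0.15 °C margins at bins 14 and 19 (continuous-time exceedance 4.04 h) |
| A(non-AC, other) | 2.0 °C | typical non-AC day peaks below 26 °C at the calibrated mean |
| A(AC, ·) | 0.2 °C | setpoint ripple, kept ≤ 0.3 °C |
| peak hour | 17.0 | late-afternoon indoor maximum; an integer peak aligns the exceedance window [15:00, 19:00) with bin boundaries, avoiding knife-edge bins |
| house effect SD | 0.8 °C | plausible dwelling heterogeneity; with 100 houses/group the SE of a pooled group mean is ≈ 0.08 °C and of a between-group difference ≈ 0.11 °C |
| sample noise SD | 0.3 °C | consumer-sensor scale; averages to ≈ 0.02 °C in a daily mean |
| away-day / incomplete-day prob. | 0.10 / 0.05 | only to exercise the occupancy and completeness filters |
| cohort size | 100 + 100 houses | two groups at the scale of the analyzed subsets |

The noise level and dwelling heterogeneity of real fleets are not publicly
characterized; these two values are assumptions and everything downstream of
them (tolerances aside) is insensitive to moderate changes. Outdoor weather
is an independent sinusoid (base 24 °C, amplitude 5 °C, +6 °C on heat-wave
dates, noise 0.5 °C) at three stations; it feeds the station-mapping stage
but no indoor–outdoor coupling is modeled.

Houses are placed with small jitter around three city anchors (Montréal,
Longueuil, Gatineau), each unambiguously nearest to one station, cycled so
every station clears the 30-house coverage minimum at the default cohort
size. Every house-day draws from its own seed sequence keyed by (seed,
house index, day index), making output files byte-identical across reruns
and independent of generation order.

What the generator does **not** emulate: thermal inertia and multi-day heat
accumulation, indoor–outdoor temperature coupling, humidity, occupancy
rhythms (motion is uniform at-random), thermostat setpoint schedules, and
missingness that correlates with heat. Passing recovery tests therefore
demonstrates that the pipeline's QC, labeling and statistics are correct
under the stated statistical structure — not that the model captures real
building physics.

## Numerical and degenerate-input choices

- Welch p-values use the Student-t CDF; tests cross-check them against an
  independent 50-digit incomplete-beta evaluation (1e-9) and a 10⁶-draw
  Monte-Carlo null (3 SE). Degenerate inputs (group size < 2, both
  variances zero) raise errors naming the offending group.
- Threshold comparisons use ≥ throughout.
- Station ties break toward the lexicographically smallest station id;
  keep-first deduplication on (house_id, timestamp); hour bins are
  half-open; all timestamps are naive local standard time (no DST), the
  convention of the weather source being emulated.
- The heat-wave calendar defaults encode the six-day June 30 – July 5
  declaration plus the August 4 Outaouais event. One narrative source
  describes the first event as "June 29 – July 3"; the calendar follows the
  declaration dates and the discrepancy is simply noted here.
- Readers never silently drop rows: every input row is parsed or rejected
  with a reason, and rejection counts are reported.

## Problem sizes used in the test suite

Unit and property tests run on a 24-house, 16-day cohort (~110 k telemetry
rows, seconds). The acceptance checks run the full PC-2018 cohort —
200 houses × 92 days ≈ 5.2 M telemetry rows — twice (once as calibrated,
once with house effects off and noise 0.1 °C for the closed-form exceedance
check); each end-to-end run takes on the order of 1–2 minutes.
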