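# Calibrated 2018 Quebec summer scenario: 100 AC + 100 non-AC houses,
# June 1 - August 31, official heat-wave calendar, 26 degC threshold.
# Run with:  heatsense run --config configs/pc2018.toml --out results/pc2018

out_dir = "pc2018_out"

[cohort]
n_ac_houses = 100
n_nonac_houses = 100
date_start = 2018-06-01
date_end = 2018-08-31
peak_hour = 17.0
house_effect_sd = 0.8
sample_noise_sd = 0.3
away_day_prob = 0.10
missing_day_prob = 0.05
rng_seed = 42

[means]           # group/day-type mean daily indoor temperature, degC
"AC/NHW" = 22.300
"AC/HW" = 22.386
"NONAC/NHW" = 22.800
"NONAC/HW" = 23.706

[amplitudes]      # diurnal half-amplitude, degC
"AC/NHW" = 0.2
"AC/HW" = 0.2
"NONAC/NHW" = 2.0
"NONAC/HW" = 2.656

[params]
threshold_c = 26.0
min_houses = 30
completeness_min_fraction = 0.8

[[calendar]]
region = "Montréal"
start = 2018-06-30
end = 2018-07-05

[[calendar]]
region = "Laval"
start = 2018-06-30
end = 2018-07-05

[[calendar]]
region = "Montérégie"
start = 2018-06-30
end = 2018-07-05

[[calendar]]
region = "Outaouais"
start = 2018-06-30
end = 2018-07-05

[[calendar]]
region = "Outaouais"
start = 2018-08-04
end = 2018-08-04
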