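# Example thermoloop pipeline configuration (all keys shown with defaults).
#
# Run with:  thermoloop run --config config/example.yaml

# Simulate a synthetic cohort instead of reading CSVs.  Set false and fill
# in the *_csv paths to analyse real data.
simulate: true
seed: 0
out_dir: thermoloop_out

# File mode inputs (ignored when simulate is true).
# observations_csv: data/observations.csv   # tidy long: animal_id, treatment,
#                                           # cohort, pair_id, timestamp, measure, value
# feed_csv: data/feed.csv                   # animal_id, day, offered_asfed_kg,
#                                           # refusals_asfed_kg, dm_fraction
# lw_csv: data/lw.csv                       # animal_id, day, lw_kg
# trial_start: "2014-07-27"                 # anchors day 1; default: first observation

# Simulated cohort size (pairs of TC/FRTN steers) and trial length in days.
n_pairs: 18
n_days: 18

# Rumen-temperature sanitization.
rt_floor: 35.0          # drop RT readings at or below this (deg C)
wc_mask: false          # mask RT after large drinking events
wc_window_min: 60.0     # masking window (minutes)
wc_threshold_l: 8.0     # drinking event size (litres)

# Feed accounting: how the fixed chaff allocation enters DMI.
chaff_policy: assume_consumed   # or prorate_refusals

# Drop day 1 from water-consumption fits (drinker-training inflation).
exclude_day1_wc: false

# Hysteresis-loop fits: one ellipse per treatment group per (x, y) pair.
ellipse_pairs:
  - [mean_rt, dmi_kg]
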