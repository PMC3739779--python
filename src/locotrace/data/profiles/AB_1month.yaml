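# AB at 1month: generative profile for the burst-and-glide swimmer.
# Calibrated so simulated cohort means of the measured pipeline quantities hit:
#   total distance  4719 cm per 60-min session
#   swimming time   2506 s per 60-min session
# Procedure: closed-form moment matching (swim time -> active fraction;
# distance -> speed scale), then deterministic bisection of burst_rate on the
# simulated 5-min event count where an event target exists, iterated under
# fixed seeds (see locotrace.calibration).
# Speeds in cm/s, bouts/durations in s, areas in mm^2, arena in mm.
strain_name: AB
age_stage: 1month
rest_bout_mean: 4.0
swim_bout_mean: 8.60058623668421
cruise_speed_mean: 1.247135673414247
cruise_speed_sd: 0.23983378334889363
burst_rate: 4.0
burst_speed_mean: 12.0
burst_duration: 0.6
body_area_mean: 134
body_area_sd: 18
arena_width: 95.0
arena_height: 60.0
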