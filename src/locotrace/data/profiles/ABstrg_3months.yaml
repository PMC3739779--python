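# ABstrg at 3months: generative profile for the burst-and-glide swimmer.
# Calibrated so simulated cohort means of the measured pipeline quantities hit:
#   total distance  10500 cm per 60-min session
#   swimming time   2500 s per 60-min session
# Procedure: closed-form moment matching (swim time -> active fraction;
# distance -> speed scale), then deterministic bisection of burst_rate on the
# simulated 5-min event count where an event target exists, iterated under
# fixed seeds (see locotrace.calibration).
# Non-reference strain: targets follow the qualitative strain ordering of the study design (plausible values).
# Speeds in cm/s, bouts/durations in s, areas in mm^2, arena in mm.
strain_name: ABstrg
age_stage: 3months
rest_bout_mean: 3.0
swim_bout_mean: 6.253429032484454
cruise_speed_mean: 3.2841333787892397
cruise_speed_sd: 0.5971151597798617
burst_rate: 4.0
burst_speed_mean: 15.0
burst_duration: 0.8
body_area_mean: 295
body_area_sd: 35
arena_width: 245.0
arena_height: 150.0
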