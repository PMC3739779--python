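# WIK at 1month: generative profile for the burst-and-glide swimmer.
# Calibrated so simulated cohort means of the measured pipeline quantities hit:
#   total distance  5600 cm per 60-min session
#   swimming time   2950 s per 60-min session
# Procedure: closed-form moment matching (swim time -> active fraction;
# distance -> speed scale), then deterministic bisection of burst_rate on the
# simulated 5-min event count where an event target exists, iterated under
# fixed seeds (see locotrace.calibration).
# Non-reference strain: targets follow the qualitative strain ordering of the study design (plausible values).
# Speeds in cm/s, bouts/durations in s, areas in mm^2, arena in mm.
strain_name: WIK
age_stage: 1month
rest_bout_mean: 4.0
swim_bout_mean: 17.526630443234147
cruise_speed_mean: 1.3630588437682398
cruise_speed_sd: 0.26212670072466154
burst_rate: 4.0
burst_speed_mean: 12.0
burst_duration: 0.6
body_area_mean: 125
body_area_sd: 16
arena_width: 95.0
arena_height: 60.0
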