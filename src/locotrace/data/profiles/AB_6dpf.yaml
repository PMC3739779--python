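# AB at 6dpf: generative profile for the burst-and-glide swimmer.
# Calibrated so simulated cohort means of the measured pipeline quantities hit:
#   total distance  881 cm per 60-min session
#   swimming time   2435 s per 60-min session
#   fast-swim count 28 events per 5-min session
# Procedure: closed-form moment matching (swim time -> active fraction;
# distance -> speed scale), then deterministic bisection of burst_rate on the
# simulated 5-min event count where an event target exists, iterated under
# fixed seeds (see locotrace.calibration).
# Speeds in cm/s, bouts/durations in s, areas in mm^2, arena in mm.
strain_name: AB
age_stage: 6dpf
rest_bout_mean: 2.5
swim_bout_mean: 4.312797398575398
cruise_speed_mean: 0.012
cruise_speed_sd: 0.002
burst_rate: 5.694091796875
burst_speed_mean: 2.0622528554842154
burst_duration: 1.2
body_area_mean: 1.2
body_area_sd: 0.15
arena_width: 15.5
arena_height: 15.5
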