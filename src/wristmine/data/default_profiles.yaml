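# Per-activity generative calibration for the synthetic wrist-sensor simulator.
#
# duration (s), heart_rate (bpm), calories_mean (cal/episode), distance_mean_m
# and speed_mean_mps come from the study cohort's published per-activity summary
# statistics. Per-second calorie/distance rates are derived at load time as
# mean total / mean duration. Step rates, skin temperature and the motion
# spectra (sinusoid amplitude/frequency pairs plus white noise, m/s^2 for
# accelerometer-like channels and deg/s for angular velocities) are not
# published for this device; the values below are chosen once as realistic for
# wrist-worn sensing (e.g. ~2 Hz gait for running, near-still sleeping) and are
# deliberately overlapping across the seated activities so that the seated
# cluster is separable mainly through its motion spectra.
eating:
  duration: {mean: 1995.7, sd: 1218.3, min: 147, max: 5134}
  heart_rate: {mean: 76.8, sd: 6.8}
  calories_mean: 41.7
  distance_mean_m: 64.8
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.05
  skin_temp_c: 33.5
  motion:
    accel: [[0.6, 0.8]]
    gyro: [[20.0, 0.8]]
    noise_accel: 0.15
    noise_gyro: 4.0
running:
  duration: {mean: 3303.1, sd: 2093.7, min: 126, max: 7794}
  heart_rate: {mean: 76.6, sd: 6.0}
  calories_mean: 94.5
  distance_mean_m: 1488.2
  speed_mean_mps: 0.6
  step_rate_steps_per_s: 2.6
  skin_temp_c: 33.0
  motion:
    accel: [[3.0, 2.0], [1.0, 3.0]]
    gyro: [[60.0, 2.0]]
    noise_accel: 0.5
    noise_gyro: 10.0
sleeping:
  duration: {mean: 20925.5, sd: 7083.4, min: 345, max: 33076}
  heart_rate: {mean: 69.7, sd: 7.5}
  calories_mean: 355.3
  distance_mean_m: 30.1
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.0
  skin_temp_c: 34.5
  motion:
    accel: [[0.05, 0.05]]
    gyro: [[1.0, 0.05]]
    noise_accel: 0.02
    noise_gyro: 0.5
classroom-session:
  duration: {mean: 5808.1, sd: 1474.0, min: 3036, max: 9613}
  heart_rate: {mean: 76.1, sd: 6.3}
  calories_mean: 109.2
  distance_mean_m: 85.8
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.02
  skin_temp_c: 33.5
  motion:
    accel: [[0.2, 0.4]]
    gyro: [[5.0, 0.4]]
    noise_accel: 0.1
    noise_gyro: 2.0
exam:
  duration: {mean: 4837.0, sd: 1774.4, min: 1641, max: 7156}
  heart_rate: {mean: 76.8, sd: 5.5}
  calories_mean: 595.3
  distance_mean_m: 129.8
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.01
  skin_temp_c: 33.5
  motion:
    accel: [[0.3, 1.2]]
    gyro: [[8.0, 1.2]]
    noise_accel: 0.12
    noise_gyro: 2.5
job:
  duration: {mean: 13713.0, sd: 15066.4, min: 1501, max: 45619}
  heart_rate: {mean: 75.0, sd: 4.9}
  calories_mean: 193.9
  distance_mean_m: 1123.5
  speed_mean_mps: 0.1
  step_rate_steps_per_s: 0.25
  skin_temp_c: 33.3
  motion:
    accel: [[0.7, 1.0], [0.2, 2.5]]
    gyro: [[15.0, 1.0]]
    noise_accel: 0.2
    noise_gyro: 4.0
homework:
  duration: {mean: 6743.5, sd: 4807.5, min: 513, max: 18338}
  heart_rate: {mean: 76.7, sd: 8.3}
  calories_mean: 138.9
  distance_mean_m: 157.4
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.02
  skin_temp_c: 33.5
  motion:
    accel: [[0.35, 1.5]]
    gyro: [[10.0, 1.5]]
    noise_accel: 0.12
    noise_gyro: 2.5
transportation:
  duration: {mean: 3918.1, sd: 2666.3, min: 310, max: 11716}
  heart_rate: {mean: 74.8, sd: 4.7}
  calories_mean: 83.5
  distance_mean_m: 743.0
  speed_mean_mps: 0.2
  step_rate_steps_per_s: 0.5
  skin_temp_c: 33.2
  motion:
    accel: [[0.8, 0.3], [0.3, 1.2]]
    gyro: [[10.0, 0.5]]
    noise_accel: 0.3
    noise_gyro: 5.0
watching TV-Series:
  duration: {mean: 4934.3, sd: 4692.5, min: 604, max: 16124}
  heart_rate: {mean: 74.3, sd: 3.1}
  calories_mean: 102.9
  distance_mean_m: 146.1
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.01
  skin_temp_c: 33.5
  motion:
    accel: [[0.1, 0.1]]
    gyro: [[2.0, 0.1]]
    noise_accel: 0.05
    noise_gyro: 1.0
reading:
  duration: {mean: 7364.0, sd: 0.0, min: 7364, max: 7364}
  heart_rate: {mean: 70.0, sd: 0.0}
  calories_mean: 171.0
  distance_mean_m: 21.0
  speed_mean_mps: 0.0
  step_rate_steps_per_s: 0.0
  skin_temp_c: 33.5
  motion:
    accel: [[0.15, 0.25]]
    gyro: [[4.0, 0.25]]
    noise_accel: 0.06
    noise_gyro: 1.5
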