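alpha_band:
- 8.0
- 14.0
out_dir: pafmod_out
preproc:
  eog_threshold_uv: 18.75
  hp_hz: 0.5
  lp_hz: 30.0
  spike_factor: 10.0
  use_ica_hook: false
seed: 3
sim:
  accuracy_logit_sd: 0.5
  accuracy_means:
    2P: 0.915
    2R: 0.925
    3P: 0.71
    3R: 0.86
  alpha_amplitude: 10.0
  aperiodic_exponent: 1.0
  baseline_paf_mean: 10.4
  baseline_paf_sd: 1.2
  blink_amplitude: 100.0
  blink_rate: 0.1
  eog_noise_amplitude: 1.0
  modulation_mean_f: 0.3
  modulation_mean_m: 0.0
  modulation_sd_f: 1.1
  modulation_sd_m: 0.7
  n_blocks: 1
  n_channels: 14
  n_females: 10
  n_males: 6
  noise_amplitude: 2.0
  paf_accuracy_r_male_relative: 0.4
  paf_trial_sd: 0.0
  posterior_channels:
  - ch01
  - ch02
  - ch03
  - ch04
  - ch05
  - ch06
  - ch07
  - ch08
  - ch09
  - ch10
  - ch11
  - ch12
  - ch13
  - ch14
  rt_means:
    2P: 654.0
    2R: 698.0
    3P: 736.0
    3R: 833.0
  rt_subject_sigma: 0.15
  rt_trial_sigma: 0.25
  sampling_rate: 512.0
  seed: 3
  timeline:
    baseline_onset: -0.5
    cue_sample_onset: 0.0
    delay_duration: 2.0
    sample_duration: 0.5
    segment_span:
    - -2.0
    - 5.5
    test_onset: 2.5
    trial_spacing: 5.5
  trials_per_block: 12
spectral:
  fmax: 20.0
  fmin: 2.0
  fstep: 0.5
  stride_s: 0.05
  window_s: 2.0
stats:
  alpha: 0.05
  n_boot: 1000
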