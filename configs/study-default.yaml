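menu: default
n_captures_per_scan: 10
seed: 0
geometry:
  n_slices: 20
  rows: 256
  cols: 256
  mm_per_px: 0.9
  slice_thickness_mm: 5.0
phantom_noise_sd: 6.0
devices:
- name: pacs-identity
  capture_scale: 1.0
  blur_sigma_px: 0.0
  quantization_step: 1
  luminance_gain: 1.0
  luminance_offset: 0.0
  sensor_noise_sd: 0.0
  gain_jitter_sd: 0.0
  dwell_s: 0.5
  fps: 30
- name: phone-a
  capture_scale: 1.25
  blur_sigma_px: 0.6
  quantization_step: 2
  luminance_gain: 1.04
  luminance_offset: 2.0
  sensor_noise_sd: 0.5
  gain_jitter_sd: 0.01
  dwell_s: 0.5
  fps: 30
- name: phone-b
  capture_scale: 1.1
  blur_sigma_px: 0.8
  quantization_step: 2
  luminance_gain: 0.97
  luminance_offset: -2.0
  sensor_noise_sd: 0.6
  gain_jitter_sd: 0.01
  dwell_s: 0.5
  fps: 30
- name: phone-c
  capture_scale: 1.0
  blur_sigma_px: 1.0
  quantization_step: 4
  luminance_gain: 1.06
  luminance_offset: 4.0
  sensor_noise_sd: 0.7
  gain_jitter_sd: 0.015
  dwell_s: 0.5
  fps: 30
- name: phone-d
  capture_scale: 0.85
  blur_sigma_px: 1.0
  quantization_step: 4
  luminance_gain: 0.94
  luminance_offset: -3.0
  sensor_noise_sd: 0.7
  gain_jitter_sd: 0.015
  dwell_s: 0.5
  fps: 30
- name: phone-e
  capture_scale: 0.9
  blur_sigma_px: 1.1
  quantization_step: 6
  luminance_gain: 1.08
  luminance_offset: 5.0
  sensor_noise_sd: 0.8
  gain_jitter_sd: 0.02
  dwell_s: 0.5
  fps: 30
critical_differences:
  volume_cc: 5.0
  sdh_width_mm: 2.0
  midline_shift_mm: 2.0
keep_frames: false
out_dir: null
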