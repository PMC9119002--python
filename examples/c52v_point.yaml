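# Single focused beam on the 128-element, 49.57 mm curvilinear probe,
# one bright point target at the 30 mm transmit focus.
probe: c52v
pulse:
  center_frequency_mhz: 3.5
  fractional_bandwidth: 0.5
medium:
  sound_speed_m_s: 1540.0
sequence:
  n_beams: 1
  span_deg: 0.0
  focal_depth_mm: 30.0
  subaperture: 32
grid:
  n_theta: 256
  max_depth_mm: 45.0
  theta_span_deg: 40.0
beamforming:
  band_mode: flat
  f_number: 0.0       # migration k-space aperture control (0 = all-pass)
  das_f_number: 2.0
  window_taper: 0.25
seed: 3
extras:
  phantom:
    field_of_view_mm: {theta_min: -0.1, theta_max: 0.1, r_min: 25.0, r_max: 40.0}
    points: [[0.0, 30.0]]     # [theta_rad, depth_mm]
    diffuse_density: 0.0
  acquisition:
    sampling_rate_mhz: 14.0
    n_samples: 1024
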