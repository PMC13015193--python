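segments:
- name: humerus
  length: 0.3370911395
  mass: 1.164
- name: forearm
  length: 0.2831808226
  mass: 0.802
- name: hand
  length: 0.19321
  mass: 0.966
muscles:
  biceps:
    name: biceps
    damping_B: 1.0
    parallel_stiffness_Kpe: 100.0
    serial_stiffness_Kse: 1000.0
    natural_length: 0.34
    initial_length: 0.33898
    max_tension: 400.0
    lt_width_Lwidth: 0.14
    lt_resting_length: 0.385
    st_amplitude: 400.0
    st_steepness: 0.2
    st_x_offset: -20.0
    st_y_offset: -4.5
    length_at_angle_lo: 0.34
    length_at_angle_hi: 0.25
    angle_lo: 0.0
    angle_hi: 120.0
  triceps:
    name: triceps
    damping_B: 1.0
    parallel_stiffness_Kpe: 100.0
    serial_stiffness_Kse: 1000.0
    natural_length: 0.345
    initial_length: 0.2725
    max_tension: 300.0
    lt_width_Lwidth: 0.35
    lt_resting_length: 0.385
    st_amplitude: 300.0
    st_steepness: 0.2
    st_x_offset: -30.0
    st_y_offset: -4.0
    length_at_angle_lo: 0.275
    length_at_angle_hi: 0.345
    angle_lo: 0.0
    angle_hi: 120.0
afferents:
  flexor_spindle:
    hill_params:
      name: flexor-spindle
      damping_B: 0.5
      parallel_stiffness_Kpe: 2.0
      serial_stiffness_Kse: 20.0
      natural_length: 0.25
      initial_length: 0.25
      max_tension: 5.0
      lt_width_Lwidth: 2.0
      lt_resting_length: 0.25
      st_amplitude: 2.0
      st_steepness: 0.4
      st_x_offset: -20.0
      st_y_offset: -0.0225
      length_at_angle_lo: 0.25
      length_at_angle_hi: 0.35
      angle_lo: 0.0
      angle_hi: 120.0
    tension_gain_kT: 200.0
    tension_rate_gain_kdT: 8.0
    rest_potential: -65.0
    gamma_gain: 0.002
    saturation: -10.0
  extensor_spindle:
    hill_params:
      name: extensor-spindle
      damping_B: 0.5
      parallel_stiffness_Kpe: 2.0
      serial_stiffness_Kse: 20.0
      natural_length: 0.275
      initial_length: 0.275
      max_tension: 5.0
      lt_width_Lwidth: 2.0
      lt_resting_length: 0.275
      st_amplitude: 2.0
      st_steepness: 0.4
      st_x_offset: -20.0
      st_y_offset: -0.0225
      length_at_angle_lo: 0.275
      length_at_angle_hi: 0.375
      angle_lo: 0.0
      angle_hi: 120.0
    tension_gain_kT: 200.0
    tension_rate_gain_kdT: 8.0
    rest_potential: -65.0
    gamma_gain: 0.002
    saturation: -10.0
  gto:
    tension_gain_kB: 0.2
    rest_potential: -65.0
    saturation: -10.0
joint:
  inertia: 0.1607710322947637
  damping: 0.3
  angle_range_deg:
  - 0.0
  - 120.0
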