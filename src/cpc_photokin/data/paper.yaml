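# Pilot-plant defaults: Aeroxide P-25 optics, ten 1.2 m x 33 mm CPC tubes,
# 30.2 L/min recirculation from a 40 L system, 0.6 g/L TiO2, 30 W/m^2 UV.
optics:
  kappa_m2kg: 174.7
  sigma_m2kg: 1295.8
  p_f: 0.11
  p_b: 0.71
  p_s: 0.045
geometry:
  tube_radius_mm: 16.5
  optical_path_mm: 33.0
  tube_length_m: 1.2
  n_tubes: 10
  acceptance_angle_deg: 90.0
  aperture_width_m: null
  optical_efficiency: 1.0
  reflectivity: 0.85
flow:
  flow_L_min: 30.2
  diameter_mm: 33.0
  kinematic_viscosity_m2_s: 1.0e-06
operating:
  c_cat_g_L: 0.6
  i0_W_m2: 30.0
  v_t_L: 40.0
kinetics:
  fit_slope: 348947.0
  fit_intercept: 25773.0
  m_exp: 0.5
  calibrate_vrpa_W: 4.86
simulation:
  n_subreactors: 100
  n_r: 50
  n_theta: 72
  illumination_model: direct-reflect
  toc0_ppm: 213.6
  t30w_min: 42.0
seed: 0
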