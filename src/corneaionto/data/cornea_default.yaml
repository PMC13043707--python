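# Four-layer cornea run configuration: published geometry and electrical
# conductivities; literature thermal properties for water-rich soft tissue.
# Raw Joule source (scale = 1, no compliance limit).
area_cm2: 1.1309733552923256
current_mA: 0.5
duration_s: 60.0
report_times_s: [10.0, 30.0, 60.0]
layers:
  - {name: tear_film,   thickness_um: 12.0,  sigma_S_per_m: 1.5,
     k_W_mK: 0.60, rho_kg_m3: 1000.0, c_J_kgK: 4180.0, w_b_per_s: 0.0, q_met_W_m3: 0.0}
  - {name: epithelium,  thickness_um: 50.0,  sigma_S_per_m: 0.0004,
     k_W_mK: 0.58, rho_kg_m3: 1050.0, c_J_kgK: 3800.0, w_b_per_s: 0.0, q_met_W_m3: 0.0}
  - {name: stroma,      thickness_um: 430.0, sigma_S_per_m: 0.25,
     k_W_mK: 0.58, rho_kg_m3: 1050.0, c_J_kgK: 3800.0, w_b_per_s: 0.0, q_met_W_m3: 0.0}
  - {name: endothelium, thickness_um: 20.0,  sigma_S_per_m: 0.0066,
     k_W_mK: 0.58, rho_kg_m3: 1050.0, c_J_kgK: 3800.0, w_b_per_s: 0.0, q_met_W_m3: 0.0}
thermal_boundary:
  h_conv_W_m2K: 10.0
  e_evap_W_m2: 0.0
  T_ambient_C: 34.0
  T_body_C: 34.0
  h_post_W_m2K: 10.0
solver:
  dt_s: 0.1
  dx_um: 2.0
  t_end_s: 60.0
  theta: 1.0
  T_baseline_C: 34.0
  source_scale: 1.0
  compliance_voltage_V: null
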