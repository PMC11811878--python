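{
  "seed": 1,
  "geometry": {"radius_um": 2.0},
  "dynamics": {
    "v_plus_um_s": 0.058,
    "v_minus_um_s": 0.085,
    "v_tm_um_s": 0.005,
    "r_cat_per_s": 0.0048,
    "r_res_per_s": 0.0063,
    "r_sever_per_s": 0.001,
    "p_cat": 0.09,
    "theta_bundle_deg": 40.0
  },
  "flexibility": {
    "persistence_length_um": 300.0,
    "deflection_step_um": 0.3,
    "min_deflection_rad": 0.001,
    "bundle_tracking_deg": 10.0
  },
  "nucleation": {
    "mode": "local_density",
    "r_app_per_s": 0.3,
    "n_dir": 24,
    "D_um2_s": 0.013,
    "r_u_per_s": 0.013,
    "d_max_um": 10.0,
    "p_acc_mt": 0.62,
    "p_acc_free": 0.02,
    "pool_size": 200,
    "t_occ_s": 90.0,
    "branch_mix": [0.31, 0.07, 0.62],
    "branch_mode_deg": 35.0
  },
  "scenario": {
    "n_bands": 4,
    "band_width_um": 1.0,
    "gap_width_um": 5.0,
    "f_cat": 3.0,
    "t_bias_end_s": "30min",
    "t_band_s": "60min",
    "t_end_s": "150min",
    "theta_bias_deg": 90.0,
    "sigma_bias_deg": 1.03
  },
  "outputs": {"sample_interval_s": "15min"}
}
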