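"""Scaled-down protoxylem band formation run.

Three phases on a small cylinder (R = 2 um, 4 bands): 30 min of biased
transverse nucleation, 30 min of local density-dependent nucleation, then
band activation (catastrophe rate tripled in the gaps). The fraction of
microtubule length inside the 1-um bands rises well above the 1/6 area
baseline as the gaps drain. Takes about a minute.
"""

from mtcortex.config import config_from_dict
from mtcortex.scenario import run_protoxylem

cfg = config_from_dict({
    "seed": 1,
    "geometry": {"radius_um": 2.0},
    "dynamics": {
        "v_plus_um_s": 0.058, "v_minus_um_s": 0.085, "v_tm_um_s": 0.005,
        "r_cat_per_s": 0.0048, "r_res_per_s": 0.0063, "r_sever_per_s": 0.001,
    },
    "flexibility": {"persistence_length_um": "inf"},
    "nucleation": {"mode": "local_density", "r_app_per_s": 0.3,
                   "pool_size": 200, "t_occ_s": 90.0},
    "scenario": {"n_bands": 4, "band_width_um": 1.0, "gap_width_um": 5.0,
                 "f_cat": 3.0, "t_bias_end_s": "30min", "t_band_s": "60min",
                 "t_end_s": "150min", "theta_bias_deg": 90.0,
                 "sigma_bias_deg": 1.03},
    "outputs": {"sample_interval_s": "15min"},
})

metrics, snapshot, _ = run_protoxylem(cfg)
cols = ["time_s", "n_mt", "total_length_um", "band_density", "gap_density",
        "populated_bands", "frac_in_bands_pct"]
print(metrics[cols].round(2).to_string(index=False))
print("\nband activation at t = 3600 s; afterwards the gap density collapses "
      "and the fraction of length in bands climbs past the 16.7% area share.")
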