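{
  "results": {
    "conf_analyze": {
      "distance_modes_A": [
        5.25,
        11.25,
        13.25
      ],
      "f_compact": 0.59825,
      "f_extended": 0.3215,
      "f_intermediate": 0.08025,
      "intra_energy_slope_kcal_per_mol_A": -2.44831731857,
      "rmsf_max_A": 0.547522009621,
      "rmsf_mean_A": 0.532422612403,
      "solvent_energy_slope_kcal_per_mol_A": 3.43521665073
    },
    "cp_fit": {
      "delta_cp_kcal_per_mol_K": -0.538577825088,
      "delta_cp_se_kcal_per_mol_K": 0.0157300955156,
      "dudt_apo": 67.3109785437,
      "dudt_holo": 66.9746586659,
      "dudt_lig": 23.0767071369,
      "dudt_wat": 22.8744491896,
      "r_squared_apo": 0.999999910042,
      "r_squared_holo": 0.999999950094,
      "r_squared_lig": 0.999999968951,
      "r_squared_wat": 0.999999819704
    },
    "eq_fit": {
      "dcp_app_ref": -0.439414362176,
      "dg_app_ref": -12.54,
      "dg_b_ref": -12.9966395194,
      "dg_eq_ref": -0.088612120621,
      "dh_app_ref": -5.78974116871,
      "dh_b": 3.7046990414,
      "dh_eq": 17.669973468,
      "ds_b": 0.0560165640142,
      "ds_eq": 0.059562587921,
      "rss": 4.05726719826,
      "se_dh_b": 0.163365283962,
      "se_dh_eq": 0.072162373977,
      "se_ds_b": null,
      "se_ds_eq": 0.000266730461438
    },
    "simulate": {
      "ensemble_frames": 120,
      "itc_n_points": 9,
      "true_delta_cp": -0.557,
      "two_state_inactive_probability": 0.409172892192
    }
  },
  "seed": 7,
  "stages": {
    "conf_analyze": "ok",
    "cp_fit": "ok",
    "eq_fit": "ok",
    "simulate": "ok"
  }
}
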