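{
  "version": 1,
  "description": "Construct preset library for proteoliposome proton-conduction assays. Barrier anchors are QM/MM lateral proton-transfer barriers; transport coefficients are the shipped calibration constants (derivations in docs/methods.md).",
  "temperature_K": 310.15,
  "acetate_attempt": 0.004,
  "atp_attempt": 1.0,
  "rate_cap_s": 1000.0,
  "leak_rate_s": 0.2,
  "residual_buffer": {"pKa": 7.05, "conc_mM": 22.6},
  "acma": {"q_max": 0.95, "half_sat": 0.938, "hill": 2.73},
  "pump": {
    "turnover_max": 2400.0,
    "stall_pmf_kcal": 4.0,
    "reference_potential_mV": 120.0,
    "copies": 1
  },
  "constructs": {
    "WT-Nqo13":    {"barrier_dg": 14.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 7.0},
    "E123Q-Nqo13": {"barrier_dg": 6.0,  "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": -5.0},
    "K235M-Nqo13": {"barrier_dg": 14.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": true,  "driving_dg": 7.0},
    "E377Q-Nqo13": {"barrier_dg": 14.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": true,  "driving_dg": 7.0},
    "WT-Nqo12dTH": {"barrier_dg": 15.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 7.0},
    "E132Q-Nqo12": {"barrier_dg": 13.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 2.0},
    "K385I-Nqo12": {"barrier_dg": 15.0, "copies_per_vesicle": 1, "electrogenic": true, "orientation_n_in": 0.75, "blocked": true,  "driving_dg": 7.0},
    "empty":       {"barrier_dg": 0.0,  "copies_per_vesicle": 0, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 0.0},
    "AqpZ":        {"barrier_dg": 0.0,  "copies_per_vesicle": 0, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 0.0},
    "F1Fo-only":   {"barrier_dg": 0.0,  "copies_per_vesicle": 0, "electrogenic": true, "orientation_n_in": 0.75, "blocked": false, "driving_dg": 0.0}
  }
}
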