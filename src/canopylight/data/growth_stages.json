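{
  "_comment": "Five observed growth stages of the maize/soybean strip system: canopy height difference h (cm) and solar elevation angle theta (deg) are field measurements; delta_deg=0 (rows along the reference planting axis), E0=1 (unit direct intensity), Df=0.15 (mid clear-day diffuse band), alpha=0.1 (soybean-row reflectance) are package defaults.",
  "three-leaf": {"h_cm": 5, "theta_deg": 33.8, "delta_deg": 0.0, "E0": 1.0, "Df": 0.15, "alpha": 0.1},
  "flowering": {"h_cm": 23, "theta_deg": 30.4, "delta_deg": 0.0, "E0": 1.0, "Df": 0.15, "alpha": 0.1},
  "podding": {"h_cm": 113, "theta_deg": 27.0, "delta_deg": 0.0, "E0": 1.0, "Df": 0.15, "alpha": 0.1},
  "seed-filling": {"h_cm": 101, "theta_deg": 21.4, "delta_deg": 0.0, "E0": 1.0, "Df": 0.15, "alpha": 0.1},
  "maturity": {"h_cm": 100, "theta_deg": 13.9, "delta_deg": 0.0, "E0": 1.0, "Df": 0.15, "alpha": 0.1}
}
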