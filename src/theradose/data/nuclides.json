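{
  "comment": "Versioned nuclear-data summary used throughout the package. Half-lives from standard evaluated nuclear data (Zr-89: 78.41 h; Lu-177: 6.647 d = 159.53 h). Emission tables are ICRP-107-style summaries: one mean charged-particle line carrying the total mean charged energy per decay, plus the principal photon lines. Gamma dose-rate constants are screening values in uSv.m2/(MBq.h).",
  "version": 1,
  "nuclides": {
    "Zr-89": {
      "half_life_h": 78.41,
      "emissions": [
        {"kind": "charged", "mean_energy_kev": 396.9, "yield": 0.2273},
        {"kind": "photon", "mean_energy_kev": 511.0, "yield": 0.4546},
        {"kind": "photon", "mean_energy_kev": 909.2, "yield": 0.9904}
      ],
      "gamma_dose_rate_constant": 0.25
    },
    "Lu-177": {
      "half_life_h": 159.53,
      "emissions": [
        {"kind": "charged", "mean_energy_kev": 147.9, "yield": 1.0},
        {"kind": "photon", "mean_energy_kev": 208.4, "yield": 0.104},
        {"kind": "photon", "mean_energy_kev": 112.9, "yield": 0.062}
      ],
      "gamma_dose_rate_constant": 0.0053
    }
  }
}
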