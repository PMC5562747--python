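{
  "description": "Calibrated pharmacodynamic defaults for the competitive-antagonism beat-rate model. Fitted to reported percent-change anchors; fitted values, not measured receptor constants.",
  "params": {
    "B0_bpm": 60.0,
    "Rmax": 0.5555603938159478,
    "EC50_uM": 0.03647674965322457,
    "Ki_uM": 0.006065078975562449,
    "hill_n": 4.421667684257461,
    "E_basal_uM": 0.026659642132850984
  },
  "calibration": {
    "rss": 4.935279483852746e-25,
    "residuals_pct": {
      "epinephrine_alone": -2.0605739337042905e-13,
      "propranolol_alone": 2.113864638886298e-13,
      "liver_recovery": 4.547473508864641e-13,
      "blocked": -4.46753745109163e-13
    },
    "anchors": [
      {
        "name": "epinephrine_alone",
        "E_uM": 0.5,
        "P_uM": 0.0,
        "target_pct": 40.0
      },
      {
        "name": "propranolol_alone",
        "E_uM": 0.0,
        "P_uM": 0.1,
        "target_pct": -10.0
      },
      {
        "name": "liver_recovery",
        "E_uM": 0.5,
        "P_uM": 0.0662337782140526,
        "target_pct": 25.0
      },
      {
        "name": "blocked",
        "E_uM": 0.5,
        "P_uM": 0.1,
        "target_pct": 5.0
      }
    ]
  }
}
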