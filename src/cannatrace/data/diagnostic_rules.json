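{
  "tol_da": 0.005,
  "tol_ppm": 10.0,
  "mass_tol_ppm": 5.0,
  "rt_margin_min": 0.3,
  "stereo_threshold": 2.0,
  "stereo_high_ratio_class": "CBE",
  "rules": [
    {
      "core_name": "CBE",
      "required_fragments": [205.1227, 135.0448],
      "description": "cannabielsoin-type core: joint presence of the m/z 205.12 and 135.04 fragment ions"
    },
    {
      "core_name": "CBDH",
      "required_fragments": [207.1380],
      "description": "hexyl-resorcinol moiety of cannabidihexol-type compounds"
    },
    {
      "core_name": "CBD",
      "required_fragments": [193.1228],
      "description": "olivetol moiety (C12H17O2+), the main CBD fragment ion"
    }
  ]
}
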