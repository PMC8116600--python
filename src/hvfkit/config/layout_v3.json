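{
  "version": "V3",
  "canonical_width": 3726,
  "canonical_height": 5262,
  "glyph_scale": 5,
  "regions": {
    "name": [
      0.02,
      0.014,
      0.32,
      0.038
    ],
    "patient_id": [
      0.02,
      0.041,
      0.32,
      0.065
    ],
    "date_of_birth": [
      0.02,
      0.068,
      0.32,
      0.092
    ],
    "test_date": [
      0.02,
      0.095,
      0.32,
      0.119
    ],
    "laterality": [
      0.34,
      0.014,
      0.64,
      0.038
    ],
    "field_size": [
      0.34,
      0.041,
      0.64,
      0.065
    ],
    "strategy": [
      0.34,
      0.068,
      0.64,
      0.092
    ],
    "foveal_sensitivity": [
      0.34,
      0.095,
      0.64,
      0.119
    ],
    "test_duration": [
      0.34,
      0.122,
      0.64,
      0.146
    ],
    "false_positive_rate": [
      0.66,
      0.014,
      0.98,
      0.038
    ],
    "false_negative_rate": [
      0.66,
      0.041,
      0.98,
      0.065
    ],
    "fixation_loss": [
      0.66,
      0.068,
      0.98,
      0.092
    ],
    "pupil_diameter": [
      0.66,
      0.095,
      0.98,
      0.119
    ],
    "refraction": [
      0.66,
      0.122,
      0.98,
      0.146
    ],
    "mean_deviation": [
      0.66,
      0.149,
      0.98,
      0.173
    ],
    "pattern_standard_deviation": [
      0.66,
      0.176,
      0.98,
      0.2
    ],
    "vfi": [
      0.66,
      0.203,
      0.98,
      0.227
    ],
    "RAW": [
      0.03,
      0.295,
      0.47,
      0.525
    ],
    "TD_VALUE": [
      0.03,
      0.535,
      0.47,
      0.765
    ],
    "PD_VALUE": [
      0.53,
      0.535,
      0.97,
      0.765
    ],
    "TD_PERC": [
      0.03,
      0.775,
      0.47,
      0.995
    ],
    "PD_PERC": [
      0.53,
      0.775,
      0.97,
      0.995
    ]
  }
}
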