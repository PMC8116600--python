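{
  "version": "V1",
  "canonical_width": 650,
  "canonical_height": 938,
  "glyph_scale": 1,
  "regions": {
    "name": [
      0.02,
      0.015,
      0.48,
      0.041
    ],
    "patient_id": [
      0.02,
      0.045,
      0.48,
      0.071
    ],
    "date_of_birth": [
      0.02,
      0.075,
      0.48,
      0.101
    ],
    "test_date": [
      0.02,
      0.105,
      0.48,
      0.131
    ],
    "laterality": [
      0.02,
      0.135,
      0.48,
      0.161
    ],
    "foveal_sensitivity": [
      0.02,
      0.165,
      0.48,
      0.191
    ],
    "false_positive_rate": [
      0.02,
      0.195,
      0.48,
      0.221
    ],
    "false_negative_rate": [
      0.02,
      0.225,
      0.48,
      0.251
    ],
    "fixation_loss": [
      0.02,
      0.255,
      0.48,
      0.281
    ],
    "test_duration": [
      0.52,
      0.015,
      0.98,
      0.041
    ],
    "field_size": [
      0.52,
      0.045,
      0.98,
      0.071
    ],
    "strategy": [
      0.52,
      0.075,
      0.98,
      0.101
    ],
    "pupil_diameter": [
      0.52,
      0.105,
      0.98,
      0.131
    ],
    "refraction": [
      0.52,
      0.135,
      0.98,
      0.161
    ],
    "mean_deviation": [
      0.52,
      0.165,
      0.98,
      0.191
    ],
    "pattern_standard_deviation": [
      0.52,
      0.195,
      0.98,
      0.221
    ],
    "vfi": [
      0.52,
      0.225,
      0.98,
      0.251
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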