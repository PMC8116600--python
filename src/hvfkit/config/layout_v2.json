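{
  "version": "V2",
  "canonical_width": 2400,
  "canonical_height": 3180,
  "glyph_scale": 3,
  "regions": {
    "test_date": [
      0.02,
      0.012,
      0.48,
      0.037
    ],
    "laterality": [
      0.02,
      0.041,
      0.48,
      0.066
    ],
    "field_size": [
      0.02,
      0.07,
      0.48,
      0.095
    ],
    "strategy": [
      0.02,
      0.099,
      0.48,
      0.124
    ],
    "foveal_sensitivity": [
      0.02,
      0.128,
      0.48,
      0.153
    ],
    "false_positive_rate": [
      0.02,
      0.157,
      0.48,
      0.182
    ],
    "false_negative_rate": [
      0.02,
      0.186,
      0.48,
      0.211
    ],
    "fixation_loss": [
      0.02,
      0.215,
      0.48,
      0.24
    ],
    "test_duration": [
      0.02,
      0.244,
      0.48,
      0.269
    ],
    "name": [
      0.52,
      0.012,
      0.98,
      0.037
    ],
    "patient_id": [
      0.52,
      0.041,
      0.98,
      0.066
    ],
    "date_of_birth": [
      0.52,
      0.07,
      0.98,
      0.095
    ],
    "pupil_diameter": [
      0.52,
      0.099,
      0.98,
      0.124
    ],
    "refraction": [
      0.52,
      0.128,
      0.98,
      0.153
    ],
    "mean_deviation": [
      0.52,
      0.157,
      0.98,
      0.182
    ],
    "pattern_standard_deviation": [
      0.52,
      0.186,
      0.98,
      0.211
    ],
    "vfi": [
      0.52,
      0.215,
      0.98,
      0.24
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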