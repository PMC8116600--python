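{
 "_comment": [
  "Mapping of report metadata fields to DICOM OPV attribute keywords.",
  "Only public attributes are used; vendor-private tags are ignored.",
  "Fields absent here (false positive/negative rates, fixation loss,",
  "field size, refraction, VFI) live inside standard sequences handled",
  "by hvfkit.dicom_ingest: VisualFieldCatchTrialSequence,",
  "FixationSequence, VisualFieldHorizontal/VerticalExtent,",
  "RefractiveParametersUsedOnPatientSequence and",
  "VisualFieldGlobalResultsIndexSequence respectively.",
  "Per-point convention: VisualFieldTestPointSequence items carry",
  "chart coordinates with x positive temporal (mirrored for OS),",
  "StimulusResults SEEN + SensitivityValue for numeric cells,",
  "NOT SEEN + SensitivityValue 0 for below-threshold ('<0') cells and",
  "NOT SEEN with no SensitivityValue for blind-spot cells."
 ],
 "fields": {
  "name": "PatientName",
  "patient_id": "PatientID",
  "date_of_birth": "PatientBirthDate",
  "test_date": "StudyDate",
  "laterality": "MeasurementLaterality",
  "foveal_sensitivity": "FovealSensitivity",
  "test_duration": "VisualFieldTestDuration",
  "strategy": "ProtocolName",
  "pupil_diameter": "PupilSize",
  "mean_deviation": "GlobalDeviationFromNormal",
  "pattern_standard_deviation": "LocalizedDeviationFromNormal"
 },
 "point_sequence": "VisualFieldTestPointSequence",
 "point_roles": {
  "x": "VisualFieldTestPointXCoordinate",
  "y": "VisualFieldTestPointYCoordinate",
  "seen": "StimulusResults",
  "sensitivity": "SensitivityValue",
  "total_deviation": "AgeCorrectedSensitivityDeviationValue",
  "pattern_deviation": "GeneralizedDefectCorrectedSensitivityDeviationValue",
  "total_deviation_probability": "AgeCorrectedSensitivityDeviationProbabilityValue",
  "pattern_deviation_probability": "GeneralizedDefectCorrectedSensitivityDeviationProbabilityValue"
 }
}
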