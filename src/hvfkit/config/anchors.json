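{
 "name": {
  "labels": ["NAME", "PATIENT NAME", "PATIENT"],
  "pattern": "[A-Z][A-Z0-9 ,.-]*",
  "threshold": 85
 },
 "patient_id": {
  "labels": ["ID", "PATIENT ID"],
  "pattern": "[A-Z0-9][A-Z0-9-]*",
  "threshold": 85
 },
 "date_of_birth": {
  "labels": ["DOB", "DATE OF BIRTH"],
  "pattern": "\\d{1,4}[-/]\\d{1,2}[-/]\\d{2,4}",
  "threshold": 85
 },
 "test_date": {
  "labels": ["TEST DATE", "DATE"],
  "pattern": "\\d{1,4}[-/]\\d{1,2}[-/]\\d{2,4}",
  "threshold": 85
 },
 "laterality": {
  "labels": ["EYE", "LATERALITY"],
  "pattern": "OD|OS|RIGHT|LEFT",
  "threshold": 85
 },
 "foveal_sensitivity": {
  "labels": ["FOVEA", "FOVEAL SENSITIVITY"],
  "pattern": "OFF|[-+]?\\d+(?:\\.\\d+)?",
  "threshold": 85
 },
 "false_positive_rate": {
  "labels": ["FALSE POS ERRORS", "FALSE POSITIVES"],
  "pattern": "\\d+(?:\\.\\d+)?\\s*%|\\d+/\\d+",
  "threshold": 85
 },
 "false_negative_rate": {
  "labels": ["FALSE NEG ERRORS", "FALSE NEGATIVES"],
  "pattern": "\\d+(?:\\.\\d+)?\\s*%|\\d+/\\d+",
  "threshold": 85
 },
 "fixation_loss": {
  "labels": ["FIXATION LOSSES", "FIXATION LOSS"],
  "pattern": "\\d+\\s*/\\s*\\d+",
  "threshold": 85
 },
 "test_duration": {
  "labels": ["TEST DURATION", "DURATION"],
  "pattern": "\\d{1,2}:\\d{2}",
  "threshold": 85
 },
 "field_size": {
  "labels": ["FIELD SIZE", "TEST PATTERN"],
  "pattern": "(?:10|24|30)\\s*-\\s*2",
  "threshold": 85
 },
 "strategy": {
  "labels": ["STRATEGY", "TEST STRATEGY"],
  "pattern": "SITA[ -]?(?:STANDARD|FASTER|FAST)",
  "threshold": 85
 },
 "pupil_diameter": {
  "labels": ["PUPIL DIAMETER", "PUPIL"],
  "pattern": "\\d+(?:\\.\\d+)?",
  "threshold": 85
 },
 "refraction": {
  "labels": ["RX USED", "REFRACTION"],
  "pattern": "[-+0-9][A-Z0-9 .,+/-]*",
  "threshold": 85
 },
 "mean_deviation": {
  "labels": ["MD", "MEAN DEVIATION"],
  "pattern": "[-+]?\\d+(?:\\.\\d+)?",
  "threshold": 85
 },
 "pattern_standard_deviation": {
  "labels": ["PSD", "PATTERN STANDARD DEVIATION"],
  "pattern": "\\d+(?:\\.\\d+)?",
  "threshold": 85
 },
 "vfi": {
  "labels": ["VFI", "VISUAL FIELD INDEX"],
  "pattern": "\\d+(?:\\.\\d+)?\\s*%?",
  "threshold": 85
 }
}
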