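{
  "marker_a": [55.39, 99.97, -1008.40],
  "marker_b": [55.28, 80.19, -1008.90],
  "reference_center": [55.34, 90.08, -1008.65],
  "rf_diameter_mm": 8.0,
  "shell_inner_diameter_mm": 16.0,
  "marker_separation_mm": 19.0,
  "units": "mm, optical-tracker world frame"
}
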