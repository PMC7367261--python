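{
  "categories": ["underweight", "overweight", "obese"],
  "columns": ["intercept", "gender", "district", "age", "height", "bmi13"],
  "beta": [
    [9.82, 0.41, 0.15, 0.45, -0.05, -0.63],
    [-7.89, 0.34, 0.10, -0.46, 0.02, 0.43],
    [-11.04, 0.40, 0.08, -1.04, 0.03, 0.76]
  ]
}
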