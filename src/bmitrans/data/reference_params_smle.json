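{
  "categories": ["underweight", "overweight", "obese"],
  "columns": ["intercept", "gender", "district", "age", "height", "bmi13"],
  "beta": [
    [9.17, 0.43, 0.14, 0.44, -0.05, -0.64],
    [-7.57, 0.34, 0.12, -0.48, 0.02, 0.43],
    [-10.20, 0.39, 0.07, -0.97, 0.03, 0.69]
  ]
}
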