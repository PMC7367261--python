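{
  "total": 96264,
  "boys": 49220,
  "girls": 47044,
  "urban": 53579,
  "rural": 42685,
  "age_counts": {"6": 13997, "7": 20711, "8": 21929, "9": 21335, "10": 12690, "11": 5602}
}
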