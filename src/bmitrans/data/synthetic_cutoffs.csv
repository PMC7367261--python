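gender,age,underweight_max,overweight_min,obese_min
0,6,12.70,18.45,19.70
0,7,13.15,18.90,20.15
0,8,13.60,19.35,20.60
0,9,14.05,19.80,21.05
0,10,14.50,20.25,21.50
0,11,14.95,20.70,21.95
1,6,13.20,18.95,20.20
1,7,13.65,19.40,20.65
1,8,14.10,19.85,21.10
1,9,14.55,20.30,21.55
1,10,15.00,20.75,22.00
1,11,15.45,21.20,22.45
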