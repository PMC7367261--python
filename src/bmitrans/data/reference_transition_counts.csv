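stratum,category13,underweight18,normal18,overweight18,obese18
overall,1,801,1928,116,95
overall,2,2140,38868,5891,2025
overall,3,74,6961,5154,3089
overall,4,77,2843,4732,14186
boys,1,353,752,70,61
boys,2,1067,17251,3326,1234
boys,3,43,3387,3000,1876
boys,4,43,1348,2681,9048
girls,1,448,1176,46,34
girls,2,1073,21617,2565,791
girls,3,31,3574,2154,1213
girls,4,34,1495,2051,5138
urban,1,388,859,60,41
urban,2,1132,19800,3195,1070
urban,3,39,3894,3067,1795
urban,4,34,1432,2949,9004
rural,1,413,1069,56,54
rural,2,1008,19068,2696,955
rural,3,35,3067,2087,1294
rural,4,43,1211,1783,5182
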