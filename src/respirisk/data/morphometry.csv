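generation,length_cm,diameter_cm,count,branching_angle_deg,gravity_angle_deg,alveolar_volume_ml
1,12.0,1.80,1,0,0,0
2,4.76,1.22,2,33,20,0
3,1.90,0.83,4,34,31,0
4,0.76,0.56,8,22,43,0
5,1.27,0.45,16,20,39,0
6,1.07,0.35,32,18,39,0
7,0.90,0.28,64,19,40,0
8,0.76,0.23,128,22,36,0
9,0.64,0.186,256,28,39,0
10,0.54,0.154,512,22,45,0
11,0.46,0.130,1024,33,43,0
12,0.39,0.109,2048,34,45,0
13,0.33,0.095,4096,37,45,0
14,0.27,0.082,8192,39,60,0
15,0.23,0.074,16384,39,60,0
16,0.20,0.066,32768,51,60,50
17,0.165,0.060,65536,45,60,100
18,0.141,0.054,131072,45,60,200
19,0.117,0.050,262144,45,60,350
20,0.099,0.047,524288,45,60,500
21,0.083,0.045,1048576,45,60,700
22,0.070,0.043,2097152,45,60,900
23,0.059,0.041,4194304,45,60,1000
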