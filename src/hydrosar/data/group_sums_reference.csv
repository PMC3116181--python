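sample,SCAA,PCAA,HAA,AcAA,AAA
1,3.13,19.82,36.13,31.45,9.28
2,2.22,19.67,44.10,24.67,14.05
3,2.70,18.37,38.14,31.00,9.95
4,3.11,18.62,32.64,35.50,7.42
5,3.39,18.31,32.95,35.56,7.58
6,1.15,14.54,44.24,27.71,11.96
7,0.88,21.35,33.55,31.06,6.74
8,2.09,18.63,41.39,25.41,13.36
9,1.26,11.31,48.84,26.34,16.62
10,1.45,9.09,55.03,23.72,18.48
11,0.97,3.05,68.97,17.68,20.04
12,1.48,7.58,43.32,35.39,11.28
13,1.14,20.90,34.53,33.37,9.24
14,1.09,30.33,36.21,20.67,10.88
15,0.63,40.51,31.63,17.59,10.62
16,0.33,51.19,25.18,15.65,8.65
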