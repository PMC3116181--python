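sample,ASX,THR,SER,GLX,PRO,GLY,ALA,CYS,VAL,MET,ILE,LEU,TYR,PHE,HIS,LYS,ARG,TRP
1,11.39,3.68,4.63,20.06,4.00,4.29,4.47,1.32,4.66,1.81,3.84,6.75,3.45,4.60,2.78,2.97,14.07,1.23
2,9.49,3.60,4.73,15.18,3.19,3.23,4.91,0.29,5.67,1.94,4.15,9.91,4.78,7.68,2.61,3.19,13.87,1.58
3,11.70,3.77,4.79,19.31,4.04,3.93,4.77,0.66,5.26,2.03,4.16,7.26,3.50,5.01,2.47,2.94,12.96,1.44
4,12.79,4.01,4.69,22.71,4.23,4.54,4.30,1.26,4.45,1.85,3.98,5.15,3.06,3.21,2.47,2.56,13.60,1.16
5,12.70,4.00,4.47,22.87,4.89,4.71,4.12,1.58,4.24,1.80,3.90,4.82,3.62,2.85,2.49,2.51,13.31,1.11
6,13.79,3.60,6.20,13.92,5.15,3.76,5.01,0.24,5.63,0.91,5.43,9.91,3.87,7.41,1.61,6.10,6.83,0.68
7,13.94,3.89,6.63,17.12,2.33,3.52,5.54,0.18,5.23,0.70,4.13,8.70,2.77,3.97,2.49,9.07,9.79,0.00
8,10.63,3.86,5.71,14.78,6.47,5.00,4.30,0.39,4.45,1.70,4.04,6.68,5.33,7.76,3.28,7.35,8.00,0.27
9,12.59,3.34,6.19,13.75,5.14,3.96,5.03,0.39,4.13,0.87,6.71,9.95,7.15,8.73,1.90,4.26,5.15,0.74
10,10.85,3.11,4.41,12.87,5.42,4.66,3.44,0.38,5.82,1.07,5.85,14.57,5.09,12.03,1.81,3.31,3.97,1.36
11,11.04,3.22,3.82,6.64,8.05,3.26,3.62,0.29,7.68,0.68,9.13,19.48,2.44,16.44,0.63,1.20,1.22,1.16
12,15.09,4.43,5.16,20.30,5.16,4.12,5.47,0.41,4.77,1.07,4.99,10.16,3.41,6.81,1.05,3.40,3.12,1.06
13,11.23,3.42,3.96,22.14,5.78,3.83,4.31,0.26,4.28,0.88,3.23,6.55,4.12,4.50,3.55,8.03,9.32,0.63
14,9.86,3.59,5.73,10.81,4.56,3.47,4.62,0.13,3.64,0.96,3.21,8.22,3.21,6.20,3.76,16.38,10.19,1.46
15,8.12,2.68,3.72,9.47,2.37,3.87,4.18,0.12,2.66,0.51,2.25,8.92,5.61,4.86,4.22,11.79,24.50,0.14
16,6.61,1.74,4.24,9.04,2.93,2.00,2.48,0.11,2.02,0.21,2.14,6.64,3.48,2.24,4.26,16.76,30.18,2.93
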