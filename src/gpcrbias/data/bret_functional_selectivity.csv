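ligand,pathway,pec50,pec50_se,emax,emax_se,logr,logr_se
5-HT,Gq,9.75,0.23,101.10,2.37,9.70,0.15
5-HT,G11,10.26,0.08,98.03,3.46,9.46,0.06
5-HT,G14,9.30,0.10,98.44,5.21,9.14,0.09
5-HT,G15,8.10,0.08,99.36,3.22,8.03,0.09
5-HT,Gi1,8.12,0.17,99.92,6.02,8.16,0.15
5-HT,Gi2,6.71,0.08,99.95,3.55,6.70,0.15
5-HT,Gi3,7.16,0.10,100,3.89,7.20,0.10
5-HT,GoA,7.02,0.08,99.99,3.33,7.01,0.15
5-HT,GoB,6.98,0.08,99.85,3.46,7.05,0.11
5-HT,Gz,8.00,0.08,94.48,3.32,8.13,0.08
5-HT,barr1,6.71,0.06,99.31,2.59,6.88,0.05
5-HT,barr2,6.75,0.04,99.70,1.85,6.84,0.05
Nitro-I,Gq,9.65,0.19,102.50,9.81,9.67,0.20
Nitro-I,G11,9.96,0.23,78.67,6.99,9.13,0.13
Nitro-I,G14,8.72,0.15,102.90,5.67,8.73,0.14
Nitro-I,G15,7.61,0.13,107.80,4.62,7.66,1.03
Nitro-I,Gi1,6.78,0.09,73.92,2.88,6.42,0.15
Nitro-I,Gi2,7.69,0.22,54.55,4.28,6.73,0.61
Nitro-I,Gi3,7.91,0.15,54.48,3.07,7.07,0.18
Nitro-I,GoA,7.27,0.24,51.01,4.45,6.64,0.51
Nitro-I,GoB,7.25,0.23,45.76,3.87,6.57,0.24
Nitro-I,Gz,7.36,0.14,100.30,5.06,8.69,0.13
Nitro-I,barr1,6.65,0.09,46.59,1.95,6.32,0.14
Nitro-I,barr2,6.55,0.11,43.78,2.15,6.15,0.12
Met-I,Gq,9.55,0.31,98.16,12.19,9.57,0.39
Met-I,G11,8.88,0.11,79.73,3.08,8.60,0.12
Met-I,G14,8.72,0.11,98.77,4.13,8.72,0.13
Met-I,G15,7.22,0.27,98.48,5.40,7.21,0.10
Met-I,Gi1,7.73,0.15,87.12,4.55,7.56,0.15
Met-I,Gi2,7.75,0.16,50.40,2.84,6.90,0.60
Met-I,Gi3,7.47,0.13,56.76,2.50,6.88,0.17
Met-I,GoA,7.14,0.19,47.38,3.50,6.25,0.33
Met-I,GoB,7.12,0.16,47.46,2.89,6.63,0.23
Met-I,Gz,7.20,0.13,82.95,4.19,8.55,0.10
Met-I,barr1,6.44,0.08,38.18,1.40,6.04,0.17
Met-I,barr2,6.02,0.05,44.96,1.10,5.63,0.12
OTV1,Gq,5.38,0.08,86.62,3.72,5.28,0.11
OTV1,G11,5.41,0.10,127.30,11.26,5.93,0.15
OTV1,G14,5.72,0.13,94.48,5.94,5.64,0.15
OTV1,G15,,,,,,
OTV1,Gi1,6.71,0.28,23.21,2.96,5.59,0.44
OTV1,Gi2,,,,,,
OTV1,Gi3,,,,,,
OTV1,GoA,,,,,,
OTV1,GoB,,,,,,
OTV1,Gz,8.12,1.81,16.44,1.52,4.67,0.90
OTV1,barr1,,,,,,
OTV1,barr2,,,,,,
OTV2,Gq,8.35,0.19,75.20,5.12,8.24,0.14
OTV2,G11,9.56,0.12,80.31,3.35,8.92,0.12
OTV2,G14,9.18,0.25,90.79,6.32,9.13,0.14
OTV2,G15,7.55,0.33,60.05,6.63,7.68,0.04
OTV2,Gi1,7.96,0.25,76.81,6.93,7.65,0.18
OTV2,Gi2,8.50,0.38,25.05,3.43,7.23,0.70
OTV2,Gi3,8.45,0.31,42.55,4.58,7.70,0.23
OTV2,GoA,8.35,0.25,29.67,2.68,7.76,0.51
OTV2,GoB,8.04,0.45,40.55,6.64,7.18,0.27
OTV2,Gz,8.12,0.21,61.83,5.17,7.89,0.31
OTV2,barr1,4.80,0.17,76.65,9.22,4.37,0.10
OTV2,barr2,6.32,0.15,45.50,3.22,5.44,0.13
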