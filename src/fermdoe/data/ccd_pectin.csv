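run_id,point_type,A,B,C,D,pectin_yield,pectin_yield_sd,pectin_yield_pred,reducing_sugar,reducing_sugar_sd,reducing_sugar_pred
1,factorial,-1,-1,-1,-1,2.72,0.16,2.67,0.03,0.01,0.08
2,factorial,1,-1,-1,-1,1.63,0.11,1.58,0.27,0.04,0.24
3,factorial,-1,1,-1,-1,3.03,0.32,2.98,0.09,0.08,0.10
4,factorial,1,1,-1,-1,1.77,0.13,1.73,0.19,0.08,0.19
5,factorial,-1,-1,1,-1,3.05,0.21,3.17,0.09,0.04,0.05
6,factorial,1,-1,1,-1,2.02,0.26,2.14,0.20,0.07,0.18
7,factorial,-1,1,1,-1,3.94,0.11,4.06,0.08,0.03,0.06
8,factorial,1,1,1,-1,2.75,0.16,2.87,0.12,0.07,0.12
9,factorial,-1,-1,-1,1,3.12,0.32,3.07,0.08,0.04,0.08
10,factorial,1,-1,-1,1,1.74,0.28,1.70,0.24,0.09,0.24
11,factorial,-1,1,-1,1,3.73,0.28,3.68,0.08,0.06,0.08
12,factorial,1,1,-1,1,2.19,0.16,2.14,0.14,0.07,0.18
13,factorial,-1,-1,1,1,2.05,0.27,2.17,0.17,0.07,0.14
14,factorial,1,-1,1,1,0.84,0.28,0.86,0.38,0.03,0.38
15,factorial,-1,1,1,1,3.24,0.21,3.36,0.11,0.08,0.14
16,factorial,1,1,1,1,1.77,0.13,1.89,0.29,0.09,0.21
17,axial,-2,0,0,0,4.46,0.18,4.37,0.02,0.00,0.01
18,axial,2,0,0,0,1.90,0.11,1.81,0.23,0.05,0.24
19,axial,0,-2,0,0,2.91,0.18,2.82,0.09,0.02,0.10
20,axial,0,2,0,0,4.25,0.21,4.16,0.05,0.00,0.05
21,axial,0,0,-2,0,1.38,0.16,1.63,0.25,0.07,0.19
22,axial,0,0,2,0,2.29,0.19,1.87,0.14,0.02,0.19
23,axial,0,0,0,-2,2.07,0.16,1.98,0.16,0.03,0.16
24,axial,0,0,0,2,1.49,0.13,1.40,0.25,0.07,0.25
25,center,0,0,0,0,1.48,0.18,1.48,0.10,0.03,0.12
26,center,0,0,0,0,1.48,0.14,1.48,0.15,0.08,0.12
27,center,0,0,0,0,1.50,0.19,1.48,0.10,0.07,0.12
28,center,0,0,0,0,1.49,0.24,1.48,0.10,0.02,0.12
29,center,0,0,0,0,1.50,0.34,1.48,0.14,0.04,0.12
30,center,0,0,0,0,1.48,0.15,1.48,0.10,0.02,0.12
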