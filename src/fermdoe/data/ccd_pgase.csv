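run_id,point_type,x1,x2,x3,x6,PGase,PGase_sd,PGase_pred
1,factorial,-1,-1,-1,-1,25.08,0.12,25.14
2,factorial,1,-1,-1,-1,23.11,0.15,22.83
3,factorial,-1,1,-1,-1,25.29,0.06,25.84
4,factorial,1,1,-1,-1,23.82,0.18,23.96
5,factorial,-1,-1,1,-1,20.91,0.21,20.93
6,factorial,1,-1,1,-1,23.25,0.06,22.50
7,factorial,-1,1,1,-1,23.62,0.12,23.70
8,factorial,1,1,1,-1,24.47,0.15,25.70
9,factorial,-1,-1,-1,1,24.32,0.18,23.66
10,factorial,1,-1,-1,1,21.36,0.09,20.92
11,factorial,-1,1,-1,1,20.87,0.08,20.29
12,factorial,1,1,-1,1,21.41,0.16,21.96
13,factorial,-1,-1,1,1,19.78,0.12,19.28
14,factorial,1,-1,1,1,28.08,0.25,28.41
15,factorial,-1,1,1,1,21.09,0.6,21.95
16,factorial,1,1,1,1,23.95,0.16,23.52
17,axial,-2,0,0,0,18.88,0.09,18.59
18,axial,2,0,0,0,17.76,0.14,17.84
19,axial,0,-2,0,0,23.11,0.06,24.48
20,axial,0,2,0,0,27.88,0.12,23.27
21,axial,0,0,-2,0,24.56,0.14,24.51
22,axial,0,0,2,0,21.02,0.13,21.86
23,axial,0,0,0,-2,25.61,0.18,25.68
24,axial,0,0,0,2,22.82,0.06,22.03
25,center,0,0,0,0,24.52,0.04,24.75
26,center,0,0,0,0,24.62,0.09,24.75
27,center,0,0,0,0,24.52,0.12,24.75
28,center,0,0,0,0,25.62,0.06,24.75
29,center,0,0,0,0,24.62,0.04,24.75
30,center,0,0,0,0,24.62,0.12,24.75
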