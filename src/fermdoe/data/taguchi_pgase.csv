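run_id,point_type,x1,x2,x3,x4,x5,x6,PGase,PGase_sd,PGase_pred
1,oa,-1,-1,-1,-1,-1,-1,11.42,0.18,11.40
2,oa,-1,-1,-1,-1,0,0,11.32,0.14,11.36
3,oa,-1,-1,-1,-1,1,1,13.05,0.09,13.00
4,oa,-1,0,0,0,-1,-1,12.84,0.19,12.89
5,oa,-1,0,0,0,0,0,11.64,0.07,11.59
6,oa,-1,0,0,0,1,1,12.89,0.15,12.92
7,oa,-1,1,1,1,-1,-1,14.64,0.23,14.62
8,oa,-1,1,1,1,0,0,12.36,0.07,12.38
9,oa,-1,1,1,1,1,1,11.86,0.18,11.90
10,oa,0,-1,0,1,-1,0,13.00,0.12,13.96
11,oa,0,-1,0,1,0,1,15.52,0.16,15.48
12,oa,0,-1,0,1,1,-1,12.86,0.09,12.84
13,oa,0,0,1,-1,-1,0,11.15,0.18,11.12
14,oa,0,0,1,-1,0,1,14.86,0.12,14.82
15,oa,0,0,1,-1,1,-1,15.24,0.18,15.14
16,oa,0,1,-1,0,-1,0,15.08,0.22,15.12
17,oa,0,1,-1,0,0,1,13.74,0.04,13.80
18,oa,0,1,-1,0,1,-1,11.69,0.16,11.71
19,oa,1,-1,1,0,-1,1,12.42,0.24,12.45
20,oa,1,-1,1,0,0,0,12.79,0.05,12.82
21,oa,1,-1,1,0,1,-1,16.48,0.12,16.52
22,oa,1,0,-1,1,-1,1,14.00,0.18,14.06
23,oa,1,0,-1,1,0,0,15.65,0.10,15.62
24,oa,1,0,-1,1,1,-1,13.45,0.12,13.48
25,oa,1,1,0,-1,-1,1,13.37,0.05,13.38
26,oa,1,1,0,-1,0,0,11.56,0.08,11.58
27,oa,1,1,0,-1,1,-1,12.65,0.15,12.64
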