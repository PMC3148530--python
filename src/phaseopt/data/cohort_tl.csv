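patient_id,p0,p1,p2,p3,p4,p5,p6,p7,p8,p9,opt_eq_ref,gain_ref_pct,gain_worst_pct
1,1.90,2.00,1.60,2.00,1.90,1.90,2.20,2.00,1.90,1.90,no,20,27
2,33.5,35.8,44.7,56.6,65.5,71.7,71.1,59.0,45.8,37.6,yes,0,53
3,1.20,1.10,1.20,1.00,1.20,1.30,1.20,1.30,1.20,1.20,no,17,23
4,5.10,6.00,5.90,6.00,6.70,6.40,6.40,6.6,6.00,5.50,yes,0,24
5,0.09,0.06,0.08,0.13,0.14,0.15,0.12,0.08,0.07,0.13,no,33,60
6,0.12,0.04,0.11,0.16,0.14,0.19,0.12,0.10,0.09,0.17,yes,67,79
7,0.25,0.23,0.22,0.22,0.22,0.23,0.24,0.24,0.24,0.24,no,12,12
8,0.30,0.30,0.36,0.41,0.44,0.43,0.42,0.44,0.42,0.31,yes,0,32
9,0.11,0.11,0.09,0.09,0.09,0.11,0.12,0.12,0.12,0.12,no,0,25
10,5.50,5.60,5.80,5.90,5.90,6.70,6.30,5.90,5.70,6.10,yes,0,18
11,2.75,2.15,1.76,1.86,1.53,1.90,2.15,1.95,2.18,2.64,no,29,44
12,5.50,5.70,5.20,5.60,4.70,3.80,4.50,4.70,4.80,5.30,no,31,33
13,0.26,0.26,0.26,0.27,0.25,0.32,0.32,0.32,0.31,0.26,no,4,22
14,0.40,0.42,0.47,0.48,0.40,0.44,0.52,0.44,0.40,0.40,yes,0,23
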