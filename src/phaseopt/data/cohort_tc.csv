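patient_id,p0,p1,p2,p3,p4,p5,p6,p7,p8,p9,opt_eq_ref,gain_ref_pct,gain_worst_pct
1,165,164,163,167,170,167,168,166,165,164,no,4,4
2,66,67,66,68,69,68,67,69,66,67,no,5,5
3,63,61,57,60,60,58,61,60,58,58,yes,0,11
4,75,91,95,91,65,70,70,72,79,74,no,27,46
5,43,41,42,41,41,40,40,38,37,40,yes,0,16
6,40,43,41,41,44,43,39,41,40,42,no,10,13
7,115,115,114,115,115,114,116,113,115,115,no,1,3
8,126,129,129,128,127,128,128,126,126,127,no,2,2
9,72,72,72,71,72,70,71,72,71,71,no,0,3
10,47,50,50,48,47,47,51,51,49,49,no,9,9
11,74,70,72,70,70,71,73,72,70,71,no,6,6
12,61,60,58,61,63,61,64,63,64,68,no,11,17
13,83,84,84,84,84,84,84,84,85,84,no,2,2
14,92,90,89,88,89,90,90,90,88,88,yes,0,5
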