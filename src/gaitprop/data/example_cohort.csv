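id,analysis,sex,age,le_fm,ss_sla,slow_speed,ss_speed,fast_speed,slow_partially_excluded
5,SL+AGRF,M,51,,-0.04,0.45,0.90,1.12,0
7,SL+AGRF,M,83,,-0.08,0.37,0.71,0.84,1
8,SL+AGRF,M,53,,0.01,,0.49,0.65,0
9,SL+AGRF,M,70,,-0.01,0.43,0.85,0.94,0
10,SL+AGRF,M,60,,-0.05,0.41,0.79,0.98,0
11,SL+AGRF,M,56,,-0.05,0.39,0.77,1.22,1
12,SL+AGRF,M,73,,-0.03,0.36,0.71,0.77,1
13,SL+AGRF,M,63,,-0.04,0.40,0.79,1.07,1
14,SL+AGRF,F,54,,0.09,0.32,0.59,0.68,1
17,SL+AGRF,M,58,,-0.01,0.49,0.96,,0
18,AGRF,M,69,,-0.04,0.39,0.77,,0
19,SL+AGRF,M,52,,0.07,0.39,0.77,0.88,1
25,SL+AGRF,M,69,,-0.03,0.37,0.71,0.84,1
26,SL+AGRF,F,68,,-0.02,0.34,0.67,0.81,1
27,SL+AGRF,F,68,,-0.02,0.42,0.81,1.05,0
29,SL+AGRF,M,70,,-0.05,0.39,0.77,0.94,1
31,SL+AGRF,M,74,,-0.07,0.35,0.68,0.96,1
32,SL+AGRF,M,56,,-0.02,0.60,1.19,,0
34,SL+AGRF,M,74,33,-0.03,0.74,1.02,1.40,1
35,SL,F,51,25,0.09,0.54,0.69,0.88,0
38,SL+AGRF,M,45,22,0.01,0.63,0.88,1.22,1
39,SL,M,52,22,-0.08,1.06,1.17,1.29,0
41,AGRF,M,45,19,0.13,0.40,0.50,0.62,1
42,SL,M,49,21,0.01,0.24,0.47,0.93,1
43,SL+AGRF,F,30,29,0.01,0.79,0.93,1.09,0
44,SL+AGRF,F,31,20,0.01,0.57,0.82,1.18,0
45,SL+AGRF,M,49,24,0.12,0.42,0.72,1.22,0
46,AGRF,M,64,16,-0.02,0.40,0.44,0.49,0
47,SL+AGRF,M,40,29,0.07,0.85,1.17,1.62,1
48,SL+AGRF,F,53,22,-0.06,0.21,0.46,1.03,1
50,SL+AGRF,F,23,27,0.03,0.51,0.88,1.51,0
51,SL+AGRF,M,58,26,0.05,0.59,0.76,0.98,1
52,SL+AGRF,M,63,19,0.03,0.59,0.71,0.86,1
53,AGRF,M,53,25,,0.66,0.78,0.92,0
54,SL+AGRF,M,49,29,0.04,0.76,1.05,1.45,0
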