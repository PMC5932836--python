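# Reference validation cohort: 25 infants with congenital heart disease.
# Peak systolic velocity (ascending aorta) by TTE vs CFD, cm/s;
# peak systolic pressure (aortic isthmus) by cardiac catheter vs CFD, mmHg.
case,psv_tte_cm_s,psv_cfd_cm_s,psp_cc_mmHg,psp_cfd_mmHg
1,160,151,94,92
2,85,100,102,96
3,100,80,123,120
4,245,231,89,92
5,130,130,133,137
6,100,92,101,103
7,120,112,121,126
8,121,100,91,95
9,240,226,92,98
10,100,90,80,86
11,100,80,88,93
12,97,81,78,82
13,110,111,118,114
14,150,142,110,106
15,131,120,110,114
16,235,248,115,122
17,150,145,81,84
18,110,132,110,115
19,75,76,115,110
20,70,71,113,114
21,212,200,117,121
22,251,231,100,97
23,250,227,110,102
24,241,227,130,131
25,240,228,106,112
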