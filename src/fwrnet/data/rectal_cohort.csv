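patient_id,disease_free_months,recurrence,survival_months,ihc_tumor,ihc_biopsy
1,0,yes,15,1,1
2,6,yes,19,1,3
3,20,yes,25,2,1
4,13,yes,40,3,3
5,37,yes,60,3,3
6,44,yes,62,2,3
7,0,yes,15,3,2
8,63,yes,75,3,3
9,26,yes,27,3,3
10,12,no,26,3,3
11,34,yes,43,2,2
12,100,yes,101,1,1
13,0,yes,180,1,3
14,114,yes,114,2,2
15,122,yes,255,3,2
16,167,yes,167,2,2
17,81,no,101,3,2
18,129,yes,129,2,3
19,129,yes,288,2,3
20,126,yes,126,3,2
21,186,yes,238,3,3
22,122,yes,122,2,2
23,168,yes,288,2,3
24,151,yes,151,3,3
25,168,yes,168,2,2
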