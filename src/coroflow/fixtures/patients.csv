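patient_id,map_mmHg,co_l_min,dominance
1,93.33,6.0,right
2,95.67,3.8,right
3,92.67,6.2,right
4,97.67,6.5,right
5,84.33,4.4,right
6,99.33,5.2,right
7,95.33,3.6,right
8,100.33,6.3,left
9,98.67,3.4,right
10,100.67,5.4,left
11,115.33,6.4,right
12,92.33,4.9,right
13,88.67,6.0,right
14,99.33,3.97,right
15,90.0,4.3,right
16,105.33,4.66,right
17,99.0,3.88,right
18,100.0,5.25,right
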