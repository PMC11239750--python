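ffr_id,patient_id,location,ffr_invasive
1,1,mLAD,0.68
2,2,mLAD,0.52
3,2,dLAD,0.46
4,2,pLCX,0.88
5,3,mLAD,0.87
6,4,pLAD,0.57
7,4,2nd diagonal LAD,0.51
8,5,LCX,0.71
9,6,pLAD,0.61
10,7,mLAD,0.59
11,8,LCX,0.38
12,9,mLAD,0.92
13,10,pRCA,0.74
14,11,pLAD,0.7
15,12,mLAD,0.8
16,13,mLAD,0.77
17,13,LCX,0.72
18,14,mRCA,0.96
19,15,mLAD,0.44
20,16,mLAD,0.78
21,16,LCX,0.52
22,17,mLAD,0.83
23,17,1st diagonal LAD,0.89
24,18,dRCA,0.84
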