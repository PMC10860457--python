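patient_id,mean_3d_mm,sd_3d_mm
1,1.76,0.70
2,1.48,0.58
3,1.49,0.81
4,2.69,1.35
5,2.36,1.07
6,2.93,1.33
7,1.43,0.34
8,2.20,0.76
9,1.14,0.63
10,2.70,1.10
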