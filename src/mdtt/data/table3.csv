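patient_id,ml_mean_mm,ml_sd_mm,si_mean_mm,si_sd_mm,ap_mean_mm,ap_sd_mm
1,0.18,0.16,0.38,0.27,0.22,0.18
2,0.46,0.66,0.69,0.96,1.00,1.32
3,0.83,0.68,0.37,0.27,1.10,0.90
4,0.43,0.32,1.34,0.73,1.72,1.42
5,0.13,0.13,1.83,1.31,0.29,0.25
6,1.55,1.26,0.51,0.46,1.55,1.65
7,0.19,0.15,0.41,0.3,0.19,0.21
8,0.28,0.32,0.42,0.24,0.37,0.26
9,0.18,0.17,0.19,0.2,0.29,0.22
10,0.74,0.45,1.00,0.69,1.49,1.05
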