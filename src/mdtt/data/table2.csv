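patient_id,ml_mean_mm,ml_sd_mm,si_mean_mm,si_sd_mm,ap_mean_mm,ap_sd_mm
1,0.89,0.58,0.90,0.37,1.48,0.86
2,0.60,0.70,0.34,0.54,0.67,0.82
3,0.46,0.57,0.46,0.50,0.36,0.41
4,0.72,0.84,1.97,2.29,0.85,1.02
5,0.46,0.57,1.44,1.57,0.49,0.67
6,1.32,1.52,2.80,2.43,2.93,2.39
7,0.44,0.54,0.23,0.31,0.76,1.09
8,0.55,0.70,0.47,0.55,0.35,0.53
9,0.34,0.41,0.49,0.54,0.71,0.80
10,1.25,1.56,1.74,0.90,1.00,0.49
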