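patient_id,sex,age,gtv_cm3,ptv_cm3,marker_dome_si_mm
1,F,81,4.7,41.2,37
2,M,78,2.3,28.9,27
3,F,85,23.1,95.6,41
4,M,67,112.5,304.8,47
5,M,72,237.6,388.7,82
6,M,77,2.8,33.5,34
7,M,63,191.3,384.7,43
8,M,73,9.1,57.6,22
9,M,73,35.8,125.15,34
10,M,70,7.3,53.4,17
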