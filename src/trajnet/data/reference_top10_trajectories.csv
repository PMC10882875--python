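rank,d1,d2,d3,median_onset_age_d1,n_12,median_t12,n_123,median_t23
1,arthritis,hypertension,dyslipidemia,44,2693,10,446,4
2,arthritis,hypertension,heart,43,2693,11,389,4
3,arthritis,hypertension,diabetes,44,2693,10,328,5
4,arthritis,digestive,heart,40,1869,10,315,7
5,arthritis,heart,dyslipidemia,44,1592,10,288,4.5
6,arthritis,digestive,chronic_lung,40,1869,10,275,5
7,digestive,heart,dyslipidemia,40,1153,10,207,5
8,hypertension,heart,dyslipidemia,52,1268,5,203,4
9,arthritis,hypertension,stroke,46,2693,10,200,5
10,arthritis,digestive,kidney,37,1869,9,197,7
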