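code,label
hypertension,Hypertension
dyslipidemia,Dyslipidemia
diabetes,Diabetes
cancer,Cancer
chronic_lung,Chronic lung diseases
liver,Liver diseases
heart,Heart diseases
stroke,Stroke
kidney,Kidney diseases
digestive,Digestive diseases
emp,Emotional and mental problems
mrd,Memory-related disease
arthritis,Arthritis
asthma,Asthma
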