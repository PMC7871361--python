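subgroup,eurocat_prevalence_per_10k
any_ca,205.7
chd,56.0
nervous_system,13.5
respiratory,1.9
orofacial_clefts,14.2
eye,5.6
ear_face_neck,5.7
digestive,20.3
abdominal_wall,2.7
urinary,28.6
genital,10.9
limb,48.4
chromosomal,15.8
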