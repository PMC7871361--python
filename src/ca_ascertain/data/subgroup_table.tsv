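subgroup	start	end	exclusions	is_chd	chd_severe	chd_septal	chd_conotruncal
nervous_system	Q00	Q07		0	0	0	0
eye	Q10	Q15		0	0	0	0
ear_face_neck	Q16	Q18		0	0	0	0
chd	Q20	Q26		1	0	0	0
chd	Q20.0	Q20.0		1	1	0	1
chd	Q20.1	Q20.1		1	0	0	1
chd	Q20.3	Q20.3		1	1	0	1
chd	Q20.4	Q20.4		1	1	0	0
chd	Q21.0	Q21.0		1	0	1	0
chd	Q21.1	Q21.1		1	0	1	0
chd	Q21.2	Q21.2		1	1	1	0
chd	Q21.3	Q21.3		1	1	0	1
chd	Q21.4	Q21.4		1	0	1	0
chd	Q22.0	Q22.0		1	1	0	0
chd	Q22.4	Q22.4		1	1	0	0
chd	Q22.5	Q22.5		1	1	0	0
chd	Q22.6	Q22.6		1	1	0	0
chd	Q23.4	Q23.4		1	1	0	0
chd	Q25.1	Q25.1		1	1	0	0
chd	Q26.2	Q26.2		1	1	0	0
respiratory	Q30	Q34		0	0	0	0
orofacial_clefts	Q35	Q37		0	0	0	0
digestive	Q38	Q45		0	0	0	0
abdominal_wall	Q79.2	Q79.3		0	0	0	0
abdominal_wall	Q79.5	Q79.5		0	0	0	0
urinary	Q60	Q64		0	0	0	0
genital	Q50	Q56		0	0	0	0
limb	Q65	Q74		0	0	0	0
other	Q27	Q28		0	0	0	0
other	Q75	Q78		0	0	0	0
other	Q79.0	Q79.1		0	0	0	0
other	Q79.4	Q79.4		0	0	0	0
other	Q79.6	Q79.9		0	0	0	0
other	Q80	Q85		0	0	0	0
other	Q89	Q89		0	0	0	0
syndromes	Q86	Q87		0	0	0	0
chromosomal	Q90	Q99		0	0	0	0
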