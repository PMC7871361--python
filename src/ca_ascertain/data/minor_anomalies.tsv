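code	label
Q17.0	Accessory auricle
Q17.3	Other misshapen ear
Q17.5	Prominent ear
Q18.1	Preauricular sinus and cyst
Q25.0	Patent ductus arteriosus
Q38.1	Ankyloglossia
Q53.1	Undescended testicle, unilateral
Q53.2	Undescended testicle, bilateral
Q53.9	Undescended testicle, unspecified
Q65.2	Congenital dislocation of hip, unspecified
Q65.3	Congenital subluxation of hip, unilateral
Q65.4	Congenital subluxation of hip, bilateral
Q65.5	Congenital subluxation of hip, unspecified
Q65.6	Congenital unstable hip
Q82.5	Congenital non-neoplastic naevus
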