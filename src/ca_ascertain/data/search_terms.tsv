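term	subgroup	icd10
anencephaly	nervous_system	Q00.0
spina bifida	nervous_system	Q05.9
hydrocephalus	nervous_system	Q03.9
congenital cataract	eye	Q12.0
coloboma	eye	Q13.0
microtia	ear_face_neck	Q17.2
branchial cleft malformation	ear_face_neck	Q18.2
hole in the heart	chd	Q21.9
ventricular septal defect	chd	Q21.0
atrial septal defect	chd	Q21.1
atrioventricular septal defect	chd	Q21.2
tetralogy of fallot	chd	Q21.3
transposition of the great arteries	chd	Q20.3
double outlet right ventricle	chd	Q20.1
common arterial trunk	chd	Q20.0
hypoplastic left heart	chd	Q23.4
coarctation of the aorta	chd	Q25.1
pulmonary valve stenosis	chd	Q22.1
aortic valve stenosis	chd	Q23.0
ebstein anomaly	chd	Q22.5
heart defect	chd	Q24.9
choanal atresia	respiratory	Q30.0
cystic lung malformation	respiratory	Q33.0
cleft lip	orofacial_clefts	Q36.9
cleft palate	orofacial_clefts	Q35.9
oesophageal atresia	digestive	Q39.0
duodenal atresia	digestive	Q41.0
hirschsprung disease	digestive	Q43.1
imperforate anus	digestive	Q42.3
gastroschisis	abdominal_wall	Q79.3
exomphalos	abdominal_wall	Q79.2
renal agenesis	urinary	Q60.2
posterior urethral valves	urinary	Q64.2
duplex kidney	urinary	Q63.0
hypospadias	genital	Q54.9
ambiguous genitalia	genital	Q56.4
club foot	limb	Q66.0
polydactyly	limb	Q69.9
syndactyly	limb	Q70.9
limb reduction defect	limb	Q71.9
craniosynostosis	other	Q75.0
diaphragmatic hernia	other	Q79.0
ichthyosis	other	Q80.9
down syndrome	chromosomal	Q90.9
edwards syndrome	chromosomal	Q91.3
patau syndrome	chromosomal	Q91.7
turner syndrome	chromosomal	Q96.9
noonan syndrome	syndromes	Q87.1
fetal alcohol syndrome	syndromes	Q86.0
marfan syndrome	syndromes	Q87.4
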