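snomed_code	icd10	icd10_text
89369001	Q00.0	Anencephaly
67531005	Q05.9	Spina bifida, unspecified
230745008	Q03.9	Congenital hydrocephalus, unspecified
79410001	Q12.0	Congenital cataract
93390002	Q13.0	Coloboma of iris
95812002	Q17.2	Microtia
235104008	Q18.2	Other branchial cleft malformations
253528005	Q21.9	Congenital malformation of cardiac septum, unspecified
399367004	Q21.0	Ventricular septal defect
399367004	Q21.1	Atrial septal defect
399367004	Q21.9	Congenital malformation of cardiac septum, unspecified
30288003	Q21.0	Ventricular septal defect
70142008	Q21.1	Atrial septal defect
360481003	Q21.2	Atrioventricular septal defect
86299006	Q21.3	Tetralogy of Fallot
204296002	Q20.3	Discordant ventriculoarterial connection
7484005	Q20.1	Double outlet right ventricle
61959006	Q20.0	Common arterial trunk
62067003	Q23.4	Hypoplastic left heart syndrome
7305005	Q25.1	Coarctation of aorta
56786000	Q22.1	Congenital pulmonary valve stenosis
60573004	Q23.0	Congenital stenosis of aortic valve
204357006	Q22.5	Ebstein anomaly
13213009	Q24.9	Congenital malformation of heart, unspecified
93248001	Q30.0	Choanal atresia
254621001	Q33.0	Congenital cystic lung
80281008	Q36.9	Cleft lip, unilateral
87979003	Q35.9	Cleft palate, unspecified
26179002	Q39.0	Atresia of oesophagus without fistula
51118003	Q41.0	Congenital absence, atresia and stenosis of duodenum
204739008	Q43.1	Hirschsprung disease
204712000	Q42.3	Congenital absence, atresia and stenosis of anus without fistula
72951007	Q79.3	Gastroschisis
18735004	Q79.2	Exomphalos
204942007	Q60.2	Renal agenesis, unspecified
253900005	Q64.2	Congenital posterior urethral valves
204962002	Q63.0	Accessory kidney
416010008	Q54.9	Hypospadias, unspecified
76916001	Q56.4	Indeterminate sex, unspecified
397932003	Q66.0	Talipes equinovarus
367506006	Q69.9	Polydactyly, unspecified
33072003	Q70.9	Syndactyly, unspecified
102491009	Q71.9	Reduction defect of upper limb, unspecified
102491009	Q72.9	Reduction defect of lower limb, unspecified
102491009	Q73.8	Other reduction defects of unspecified limb
57148006	Q75.0	Craniosynostosis
17190001	Q79.0	Congenital diaphragmatic hernia
13059002	Q80.9	Congenital ichthyosis, unspecified
41040004	Q90.0	Trisomy 21, meiotic nondisjunction
41040004	Q90.9	Down syndrome, unspecified
51500006	Q91.3	Trisomy 18, unspecified
765325002	Q91.7	Trisomy 13, unspecified
38804009	Q96.9	Turner syndrome, unspecified
205824006	Q87.1	Noonan syndrome
205788004	Q86.0	Fetal alcohol syndrome (dysmorphic)
19346006	Q87.4	Marfan syndrome
195967001	J45.9	Asthma, unspecified
43116000	L20.9	Atopic dermatitis, unspecified
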