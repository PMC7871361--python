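read_code	term	snomed_code
P200.	anencephaly	89369001
P10..	spina bifida	67531005
P23..	hydrocephalus	230745008
P341.	congenital cataract	79410001
P332.	coloboma	93390002
P361.	microtia	95812002
P382.	branchial cleft malformation	235104008
P579.	hole in the heart	253528005
P540.	ventricular septal defect	30288003
P541.	atrial septal defect	70142008
P542.	atrioventricular septal defect	360481003
P530.	tetralogy of fallot	86299006
P510.	transposition of the great arteries	204296002
P512.	double outlet right ventricle	7484005
P500.	common arterial trunk	61959006
P562.	hypoplastic left heart	62067003
P632.	coarctation of the aorta	7305005
P551.	pulmonary valve stenosis	56786000
P561.	aortic valve stenosis	60573004
P552.	ebstein anomaly	204357006
P5z..	heart defect	13213009
P700.	choanal atresia	93248001
P742.	cystic lung malformation	254621001
P811.	cleft lip	80281008
P801.	cleft palate	87979003
P830.	oesophageal atresia	26179002
P841.	duodenal atresia	51118003
P862.	hirschsprung disease	204739008
P871.	imperforate anus	204712000
PA62.	gastroschisis	72951007
PA61.	exomphalos	18735004
P901.	renal agenesis	204942007
P943.	posterior urethral valves	253900005
P912.	duplex kidney	204962002
P961.	hypospadias	416010008
P974.	ambiguous genitalia	76916001
PE10.	club foot	397932003
PE33.	polydactyly	367506006
PE34.	syndactyly	33072003
PE50.	limb reduction defect	102491009
PF02.	craniosynostosis	57148006
PFA0.	diaphragmatic hernia	17190001
PG30.	ichthyosis	13059002
PJ00.	down syndrome	41040004
PJ10.	edwards syndrome	51500006
PJ11.	patau syndrome	765325002
PJ30.	turner syndrome	38804009
PK21.	noonan syndrome	205824006
PK80.	fetal alcohol syndrome	205788004
PK40.	marfan syndrome	19346006
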