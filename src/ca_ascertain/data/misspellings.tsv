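term	variant
spina bifida	spina biffida
spina bifida	spinabifida
hydrocephalus	hydrocephalis
hydrocephalus	hidrocephalus
hole in the heart	whole in the heart
ventricular septal defect	ventricular septal defact
ventricular septal defect	ventriculer septal defect
atrial septal defect	atrial septal defact
tetralogy of fallot	tetrology of fallot
coarctation of the aorta	coartation of the aorta
hypoplastic left heart	hypoplastic left hart
cleft palate	cleft pallate
cleft lip	cleft lipp
oesophageal atresia	esophageal atresia
hirschsprung disease	hirschprung disease
gastroschisis	gastroskisis
exomphalos	exompholos
hypospadias	hypospadius
club foot	clubfoot
polydactyly	polydactally
syndactyly	sindactyly
down syndrome	downs syndrome
down syndrome	down s syndrome
turner syndrome	turners syndrome
diaphragmatic hernia	diaphragmatic hernea
heart defect	hart defect
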