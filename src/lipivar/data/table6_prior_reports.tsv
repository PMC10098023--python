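gene	rsid	ref	alt	freq_crwgs	freq_all	sig_all	freq_eur	sig_eur	freq_eas	sig_eas	freq_afr	sig_afr	freq_amr	sig_amr	association	source
ABCA1	rs9282541	G	A	0.05252	0.00599	1	-	0	-	0	0.00075	1	0.04178	0	Allele A found mostly in Native Americans and their descendants; negative correlation between early development of coronary disease and HDL-C levels	Mexican ABCA1 population study
ABCG8	rs4245791	C	T	0.74806	0.84105	1	0.68986	0	0.99603	1	0.89334	1	0.80259	0	GWAS association between the C allele and LDL levels in Latin Americans	US-Hispanic lipid GWAS
CELSR2	rs12740374	G	T	0.21511	0.19548	0	0.21272	0	0.04265	1	0.24735	0	0.20461	0	GWAS association between the T allele and LDL and cholesterol levels in Latin Americans	US-Hispanic lipid GWAS
LPL	rs1231383321	C	A	0.00194	-	0	-	0	-	0	-	0	-	0	Allele A found in Costa Ricans with severe hyperlipidemia	Costa Rica hypertriglyceridemia LPL study
LPL	rs118204057	G	A	0.00583	0.00019	0	-	0	-	0	-	0	0.00144	0	Allele A found in Costa Ricans with severe hyperlipidemia	Costa Rica hypertriglyceridemia LPL study
LPL	rs268	A	G	0.03307	0.00519	1	0.01391	0	-	0	0.00075	1	0.01152	0	Allele A found in Costa Ricans with severe hyperlipidemia	Costa Rica hypertriglyceridemia LPL study
LPL	rs316	C	A	0.19455	0.15255	0	0.12027	0	0.11210	1	0.23676	0	0.14553	0	Allele A found in Costa Ricans with severe hyperlipidemia	Costa Rica hypertriglyceridemia LPL study
LPL	rs328	C	G	0.07198	0.09245	0	0.13021	0	0.12202	0	0.06127	0	0.06340	0	Allele G associated in Costa Ricans with a lower risk for myocardial infarction	Costa Rica Heart Study
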