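gene	rsid	ref	alt	freq_crwgs	freq_all	sig_all	freq_afr	sig_afr	freq_eur	sig_eur	freq_amr	sig_amr	freq_eas	sig_eas	sources	clinvar_traits	gwas_traits	teslovich_traits
ABCA1	rs766619359	C	T	0.00778	-	0	-	0	-	0	-	0	-	0	S,P,R,C
ABCG8	rs11887534	G	C	0.05038	0.06050	0	0.07639	0	0.07952	0	0.09654	0	0.01388	0	S,P	SITOSTEROLEMIA	C-reactive protein levels or LDL-cholesterol levels (pleiotropy)	Cholesterol, total|Low-density lipoprotein cholesterol
ABCG8	rs200433692	C	T	0.00581	0.00039	0	-	0	-	0	0.00288	0	-	0	S,P,C
APOA5	rs3135506	G	C	0.09143	0.05571	0	0.06732	0	0.06759	0	0.11671	0	-	0	S,P	Familial hypertriglyceridemia	Low density lipoprotein cholesterol levels|High density lipoprotein cholesterol levels|Total cholesterol levels|Total triglycerides levels
APOE	rs7412	C	T	0.06614	0.07507	0	0.10287	0	0.06262	0	0.04755	0	0.10019	0	S,P,R	Apolipoproteinemia E1|atorvastatin response - Efficacy|Familial type 3 hyperlipoproteinemia|Hypercholesterolemia	Cholesterol, total|HDL cholesterol|High density lipoprotein cholesterol levels|LDL cholesterol|Lipid metabolism phenotypes|Lipoprotein A levels|Lipoprotein-associated phospholipase A2 activity change in response to darapladib treatment in|Response to statins (LDL cholesterol change)|Triglyceride levels
APOH	rs1801689	A	C	0.03112	0.01637	0	0.00151	1	0.04075	0	0.03602	0	0.00099	1	S,P,R
APOL1	rs775820342	G	A	0.00389	-	0	-	0	-	0	-	0	-	0	S,P,C
CD36	rs146027667	G	T	0.00389	-	0	-	0	-	0	-	0	-	0	S,P,R
CELSR2	rs202022169	T	C	0.01937	0.00079	1	-	0	-	0	0.00432	0	-	0	S,P,R
CELSR2	rs1203365203	G	A	0.00387	-	0	-	0	-	0	-	0	-	0	S,P,C
CREB3L3	rs779860332	C	A	0.00389	-	0	-	0	-	0	-	0	-	0	S,P,R,C
GCKR	rs146175795	G	A	0.01162	0.00439	0	-	0	-	0	0.02161	0	0.00694	0	S,R,C	Hypertriglyceridemia
LCAT	rs4986970	A	T	0.00778	0.00838	0	0.00151	0	0.02683	0	0.00720	0	-	0	S,P,R	LCAT deficiency	Apolipoprotein A1 levels|Total cholesterol levels
LDLR	rs148698650	G	A	0.00389	0.00079	0	0.00075	0	-	0	0.00288	0	-	0	S,R	Familial hypercholesterolemia
LIPE	rs1166099993	G	A	0.00389	-	0	-	0	-	0	-	0	-	0	S,P,C
LPL	rs118204057	G	A	0.00583	0.00019	0	-	0	-	0	0.00144	0	-	0	P,R	Hyperlipidemia, familial combined, LPL related|Hyperlipoproteinemia, type I	High density lipoprotein cholesterol levels|Triglyceride levels
PPARA	rs1800206	C	G	0.03501	0.02276	0	0.00529	1	0.05864	0	0.03458	0	-	0	S,R	HYPERAPOBETALIPOPROTEINEMIA, SUSCEPTIBILITY TO
SCARB1	rs748231262	G	A	0.00389	-	0	-	0	-	0	-	0	-	0	S,P,R,C	Familial hypercholesterolemia
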