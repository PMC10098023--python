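gene	rsid	ref	alt	freq_crwgs	freq_all	sig_all	freq_eur	sig_eur	freq_eas	sig_eas	freq_afr	sig_afr	freq_amr	sig_amr	clinvar_traits	gwas_traits
APOB	rs1042034	C	T	0.76163	0.62959	1	0.78230	0	0.27976	1	0.87594	1	0.74927	0	Warfarin response
APOB	rs1367117	G	A	0.34496	0.16932	1	0.29821	0	0.11507	1	0.07791	1	0.28674	0	Warfarin response	Medication use HMG CoA reductase inhibitors
APOB	rs679899	G	A	0.40116	0.48502	0	0.47415	0	0.86408	1	0.13010	1	0.39193	0	Warfarin response
APOB	rs693	G	A	0.44961	0.25099	1	0.44234	0	0.06150	1	0.20953	1	0.37752	0	Warfarin response
MTTP	rs3816873	T	C	0.27432	0.24980	0	0.26043	0	0.13591	1	0.26096	0	0.17867	0	Metabolic syndrome, potection against
APOE	rs429358	T	C	0.07004	0.15055	1	0.15506	1	0.08630	0	0.26777	1	0.10374	0	Warfarin response
APOE	rs7412	C	T	0.06615	0.07507	0	0.06262	0	0.10019	0	0.10287	0	0.04755	0	atorvastatin response - Efficacy|Warfarin response	Response to statins (LDL cholesterol change)|Lipoprotein-associated phospholipase A2 activity change in response to darapladib treatment in cardiovascular disease
APOE	rs769450	G	A	0.31712	0.32727	0	0.41153	0	0.21825	0	0.35022	0	0.29682	0	Warfarin response
HMGCR	rs17238540	T	G	0.01362	0.03554	0	0.01689	0	-	0	0.10816	1	0.02449	0	Statins, attenuated cholesterol lowering by
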