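gene	rsid	ref	alt	consequence	freq_crwgs	count_crwgs	n_hom_alt_samples	freq_1kgp_all	freq_gnomad_exomes
APOC4	rs5164	G	A	stop_gained	0.0019	1	0	0.0027	0.0004
APOL3	rs132642	T	A	start_lost	0.9027	464	2	0.0584	0.1146
APOL4	rs192225524	C	A	stop_gained	0.0311	16	0	0.0009	0.0005
CD36	rs3211938	T	G	stop_gained	0.0019	1	0	0.0309	0.0061
GCKR	rs146053779	C	T	stop_gained	0.0096	5	0	0.0014	0.0009
GPD1	rs144009925	A	G	start_lost	0.0039	2	0	-	0.0003
LPL	rs328	C	G	stop_gained	0.0719	37	2	0.0924	0.0921
SCARB1	rs749801989	T	C	start_lost	0.0116	6	0	-	0.0001
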