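ABCA1
ABCG1
ABCG4
ABCG5
ABCG8
ABHD5
ANGPTL3
APOA1
APOA2
APOA4
APOA5
APOB
APOC1
APOC2
APOC3
APOC4
APOD
APOE
APOF
APOH
APOL1
APOL2
APOL3
APOL4
APOL5
APOL6
APOM
APOO
CD36
CELSR2
CETP
CILP2
CREB3L3
CYP26A1
FADS1
FADS2
FADS3
GALNT2
GCKR
GPD1
GPIHBP1
HMGCR
KLHL8
LCAT
LDLR
LDLRAP1
LIPA
LIPC
LIPE
LIPG
LMF1
LPL
LRP1
MLXIPL
MTTP
MYLIP
NCAN
NPC1L1
PCSK9
PLA2G7
PLIN1
PLTP
PNPLA2
PPARA
SCARB1
SORT1
STAP1
TRIB1
USF1
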