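metric	total	snv	indel
variants_identified	2600	2460	140
not_in_dbsnp	47	44	3
in_dbsnp	2553	2416	137
multiallelic	75	37	38
biallelic	2525	2423	102
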