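target	organism	primer	sequence_5p_3p
m.13513G>A	Homo sapiens	F	GGGTCCATCATCCACAACCTT
m.13513G>A	Homo sapiens	R-mut	GCGGTTTCGATGATGTGGTT
m.13513G>A	Homo sapiens	R-all	TTGCGGTTTCGATGATGTGG
m.8344A>G	Homo sapiens	F	AAACCACAGTTTCATGCCC
m.8344A>G	Homo sapiens	R-mut	CACTGTAAAGAGGTGTTGGC
m.8344A>G	Homo sapiens	R-all	TTCACTGTAAAGAGGTGTTGG
B2M	Homo sapiens	F	GACTTGTCTTTCAGCAAGGA
B2M	Homo sapiens	R	ACAAAGTCACATGGTTCACA
m.5024C>T	Mus musculus	F	AGCTATCATAAGCACAATAACCC
m.5024C>T	Mus musculus	R-mut	AATAGATGTAGGATGAAGTCTTACGA
m.5024C>T	Mus musculus	R-all	CAATAGATGTAGGATGAAGTCTTACA
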