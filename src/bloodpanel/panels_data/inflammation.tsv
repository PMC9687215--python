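rank	feature_id	gene_symbol
1	C5	C5
2	IL10RA	IL10RA
3	IL17RA	IL17RA
4	IL8	IL8
5	LIF	LIF
6	SERPING1	SERPING1
7	TNF	TNF
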