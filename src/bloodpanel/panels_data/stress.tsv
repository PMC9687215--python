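rank	feature_id	gene_symbol
1	CRYAB	CRYAB
2	FTH1	FTH1
3	FTL	FTL
4	GAPDH	GAPDH
5	HSP90AB1	HSP90AB1
6	HSPB1	HSPB1
7	PTGS1	PTGS1
8	PTGS2	PTGS2
9	TFRC	TFRC
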