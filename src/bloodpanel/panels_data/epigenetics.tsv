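rank	feature_id	gene_symbol
1	DNMT1	DNMT1
2	DNMT3A	DNMT3A
3	HDAC1	HDAC1
4	HDAC6	HDAC6
5	MBD2	MBD2
6	SIRT1	SIRT1
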