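rank	feature_id	gene_symbol
1	C5	C5
2	IL10RA	IL10RA
3	IL17RA	IL17RA
4	IL8	IL8
5	LIF	LIF
6	SERPING1	SERPING1
7	TNF	TNF
8	DNMT1	DNMT1
9	DNMT3A	DNMT3A
10	HDAC1	HDAC1
11	HDAC6	HDAC6
12	MBD2	MBD2
13	SIRT1	SIRT1
14	CRYAB	CRYAB
15	FTH1	FTH1
16	FTL	FTL
17	GAPDH	GAPDH
18	HSP90AB1	HSP90AB1
19	HSPB1	HSPB1
20	PTGS1	PTGS1
21	PTGS2	PTGS2
22	TFRC	TFRC
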