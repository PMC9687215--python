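rank	feature_id	gene_symbol
1	MRPS15	MRPS15
2	CIRBP	CIRBP
3	HELZ2/PRIC285	HELZ2/PRIC285
4	MRVI1	MRVI1
5	SLC35A2	SLC35A2
6	ASXL1	ASXL1
7	KIR3DL3	KIR3DL3
8	PTK2B	PTK2B
9	FAM102A	FAM102A
10	SIK3	SIK3
11	PTGDS	PTGDS
12	BHLHE40	BHLHE40
13	UBE3A	UBE3A
14	EPB41L2	EPB41L2
15	LILRB1	LILRB1
16	PTGDS	PTGDS
17	PTGDS	PTGDS
18	LOC100510080	LOC100510080
19	LOC100510377	LOC100510377
20	IGHG1	IGHG1
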