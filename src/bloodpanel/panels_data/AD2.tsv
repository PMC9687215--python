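rank	feature_id	gene_symbol
1	RPS25	RPS25
2	UFC1	UFC1
3	HLA-A/HLA-A29allele	HLA-A/HLA-A29allele
4	HFE/HLA-H	HFE/HLA-H
5	CD72	CD72
6	RPL36AL	RPL36AL
7	MS4A7	MS4A7
8	UQCRH	UQCRH
9	RPS27A	RPS27A
10	DCAF5/WDR22	DCAF5/WDR22
11	NDUFS5	NDUFS5
12	NDUFA1	NDUFA1
13	C19orf12	C19orf12
14	COTL1	COTL1
15	MRPL51	MRPL51
16	KIAA0907/KHDC4	KIAA0907/KHDC4
17	RPS25P6	RPS25P6
18	LOC646200	LOC646200
19	RPS23P8	RPS23P8
20	RPL36AL	RPL36AL
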