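rank	feature_id	gene_symbol
1	ELOVL4	ELOVL4
2	CECR1	CECR1
3	PITHD1/C1orf128	PITHD1/C1orf128
4	LDLR	LDLR
5	CENPV/PRR6	CENPV/PRR6
6	DHRS4L2	DHRS4L2
7	PPP1R13L	PPP1R13L
8	MFN2	MFN2
9	MEAF6/C1orf149	MEAF6/C1orf149
10	SIAH2	SIAH2
11	OR51S1	OR51S1
12	TSC22D1	TSC22D1
13	HPSE	HPSE
14	DAPK2	DAPK2
15	GPR34	GPR34
16	GEMIN6	GEMIN6
17	OVCA2	OVCA2
18	NSUN7	NSUN7
19	THRA	THRA
20	ENTPD4	ENTPD4
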