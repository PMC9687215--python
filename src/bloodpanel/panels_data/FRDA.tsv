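rank	feature_id	gene_symbol
1	ABCA1	ABCA1
2	HLA-DRB1	HLA-DRB1
3	FKBP1A	FKBP1A
4	SULT1A1	SULT1A1
5	SERPINE2	SERPINE2
6	TUBB1	TUBB1
7	NDUFAF3	NDUFAF3
8	NUDT3	NUDT3
9	RARRES3	RARRES3
10	OSCAR	OSCAR
11	VSTM1	VSTM1
12	MRPL2	MRPL2
13	NUDT18	NUDT18
14	TAPBP	TAPBP
15	ZFP36L2	ZFP36L2
16	HPSE	HPSE
17	IGFBP3	IGFBP3
18	VARS2	VARS2
19	SASH1	SASH1
20	OSCAR	OSCAR
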