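rank	feature_id	gene_symbol
1	FNDC1	FNDC1
2	SOCS6	SOCS6
3	ANXA2	ANXA2
4	FYN	FYN
5	CRK	CRK
6	UBE2D3	UBE2D3
7	DCBLD2	DCBLD2
8	SESN3	SESN3
9	HIVEP3	HIVEP3
10	MCM3	MCM3
11	SEPSECS	SEPSECS
12	FECH	FECH
13	FANCD2	FANCD2
14	LONP2	LONP2
15	DDX42	DDX42
16	UBFD1	UBFD1
17	FBXL20	FBXL20
18	COL4A3	COL4A3
19	CENPK	CENPK
20	CLPTM1	CLPTM1
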