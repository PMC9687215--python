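rank	feature_id	gene_symbol
1	ATP5I	ATP5I
2	ABCA1	ABCA1
3	QPCT	QPCT
4	CNPY3	CNPY3
5	VIM	VIM
6	CTSZ	CTSZ
7	C5AR1	C5AR1
8	HNRNPUL2	HNRNPUL2
9	CHKB	CHKB
10	ARF4	ARF4
11	SLC40A1	SLC40A1
12	CREBBP	CREBBP
13	PPP2R5A	PPP2R5A
14	CAPZA2	CAPZA2
15	VPS13C	VPS13C
16	NRIP1	NRIP1
17	CD82	CD82
18	BRI3	BRI3
19	LAMTOR1/C11orf59	LAMTOR1/C11orf59
20	RORA	RORA
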