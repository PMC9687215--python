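rank	feature_id	gene_symbol
1	ACAA1	ACAA1
2	ARHGAP30	ARHGAP30
3	IKBIP/IKIP	IKBIP/IKIP
4	AIF1	AIF1
5	SPECC1L/CYTSA	SPECC1L/CYTSA
6	BRMS1	BRMS1
7	ISG15	ISG15
8	RNF44	RNF44
9	HIST1H4C	HIST1H4C
10	PPP3R1	PPP3R1
11	MYLPF/MRLC2	MYLPF/MRLC2
12	ZFP36L2	ZFP36L2
13	CX3CR1	CX3CR1
14	ATP2B4	ATP2B4
15	TMEM131	TMEM131
16	NIN	NIN
17	S100A4	S100A4
18	RPS15A	RPS15A
19	HLA-DRA	HLA-DRA
20	ZMIZ1	ZMIZ1
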