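rank	feature_id	gene_symbol
1	PET100	PET100
2	KLF6	KLF6
3	SNURF	SNURF
4	UPK3BL	UPK3BL
5	LCN2	LCN2
6	NGFRAP1	NGFRAP1
7	DEFA3	DEFA3
8	POLR1D	POLR1D
9	FYN	FYN
10	PRDX6	PRDX6
11	MS4A7	MS4A7
12	RUFY1	RUFY1
13	KLF2	KLF2
14	ATF6	ATF6
15	DUSP1	DUSP1
16	PPM1F	PPM1F
17	PTCRA	PTCRA
18	METRNL	METRNL
19	FBP1	FBP1
20	DEFA1B	DEFA1B
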