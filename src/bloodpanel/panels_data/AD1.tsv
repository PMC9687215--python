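rank	feature_id	gene_symbol
1	TFDP1	TFDP1
2	ATP5I	ATP5I
3	CMTM2	CMTM2
4	DDIT4	DDIT4
5	RPL36AL	RPL36AL
6	APBB3	APBB3
7	NDUFS5	NDUFS5
8	ING3	ING3
9	GRAP	GRAP
10	SNTB2	SNTB2
11	STIP1	STIP1
12	MED16	MED16
13	NDUFA1	NDUFA1
14	AATF	AATF
15	CDK10	CDK10
16	SHFM1	SHFM1
17	CETN2	CETN2
18	TPM3	TPM3
19	MRPL51	MRPL51
20	LOC646200	LOC646200
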