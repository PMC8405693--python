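accession	gene	fold_change	q_value	pass_rate
Q9UQ35	SRRM2	3.03	0.032	0.62
O14744	PRMT5	2.61	0.073	0.66
P51692	STAT5B	2.08	0.047	0.66
Q8NBJ7	SUMF2	1.95	0.174	0.84
P04004	VTN	1.73	0.047	1
Q9UNN8	EPCR	1.67	0.188	0.88
P10809	HSPD1	0.75	0.073	1
P25705	ATP5F1A	0.72	0.073	1
P06576	ATP5F1B	0.71	0.094	0.96
P09622	DLD	0.62	0.109	0.62
P30084	ECHS1	0.58	0.073	1
P49327	FASN	0.5	0.109	0.68
Q16836	HADH	0.49	0.105	0.76
Q9BQS8	FYCO1	0.47	0.032	0.8
P60228	EIF3E	0.47	0.085	0.96
Q9NTX5	ECHDC1	0.47	0.047	1
P10515	DLAT	0.46	0.073	1
P31040	SDHA	0.45	0.032	1
Q9H098	FAM107B	0.39	0.032	0.74
P52815	MRPL1	0.38	0.032	1
Q9H488	POFUT1	0.35	0.015	0.96
P54826	GAS1	0.34	0.015	0.68
P46060	RANBP1	0.02	0.047	0.94
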