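# Published variation-site classification across the four P. sinensis strains
# (gap/missing columns excluded from totals).
element	total_sites	invariable	variable	singleton	parsimony_informative	pct_variable
Complete genome	17064	16581	483	436	47	2.83
tRNAs	1541	1516	25	22	3	1.62
rRNAs	2580	2536	44	44	0	1.71
D-loop	1546	1433	113	74	39	7.31
ATP6	684	668	16	16	0	2.34
ATP8	165	159	6	6	0	3.64
COX1	1545	1512	33	32	1	2.14
COX2	687	675	12	12	0	1.75
COX3	784	766	18	17	1	2.30
Cytb	1140	1113	27	25	2	2.37
NAD1	972	947	25	25	0	2.57
NAD2	1041	1013	28	26	2	2.69
NAD3	350	339	11	11	0	3.14
NAD4	1381	1340	41	41	0	2.97
NAD4L	297	286	11	11	0	3.70
NAD5	1779	1734	45	45	0	2.53
NAD6	525	507	18	18	0	3.43
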