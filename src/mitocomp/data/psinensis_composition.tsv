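# Published average base composition (%) and skews per mitogenome element,
# averaged over the four P. sinensis strains.
element	pct_T	pct_C	pct_A	pct_G	pct_AT	pct_GC	at_skew	gc_skew
tRNAs	28.21	21.67	34.90	15.22	63.11	36.89	0.11	-0.17
rRNAs	22.16	22.45	39.24	16.16	61.40	38.61	0.28	-0.16
D-loop	31.78	25.70	32.54	9.99	64.32	35.69	0.01	-0.44
ATP6	30.34	24.71	36.37	8.59	66.71	33.30	0.09	-0.48
ATP8	29.55	25.00	40.76	4.70	70.31	29.70	0.16	-0.68
COX1	30.91	23.53	29.92	15.65	60.83	39.18	-0.02	-0.20
COX2	27.62	23.94	36.64	11.79	64.26	35.73	0.14	-0.34
COX3	27.01	26.05	32.27	14.67	59.28	40.72	0.09	-0.28
Cytb	27.43	28.57	33.22	10.77	60.65	39.34	0.10	-0.45
NAD1	31.48	25.62	31.97	10.93	63.45	36.55	0.01	-0.40
NAD2	25.07	26.51	40.71	7.71	65.78	34.22	0.24	-0.55
NAD3	31.79	25.71	33.21	9.29	65.00	35.00	0.02	-0.47
NAD4	27.75	26.90	36.44	8.91	64.19	35.81	0.14	-0.50
NAD4L	30.89	26.43	34.01	8.67	64.90	35.10	0.05	-0.51
NAD5	26.25	29.06	35.26	9.43	61.51	38.49	0.15	-0.51
NAD6	13.29	31.28	48.50	6.95	61.79	38.23	0.57	-0.64
PCGs	27.64	26.41	36.10	9.85	63.74	36.26	0.13	-0.46
Complete genome	27.23	25.45	35.56	11.75	62.79	37.20	0.13	-0.37
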