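# Published per-element lengths, intergenic spacers (negative = overlap with the
# next element) and PCG start/stop codons for the four P. sinensis strains
# (HB, JB, RB, WB). Coordinates are reconstructed by cumulative walking from
# tRNA-Phe at position 1; the walk closes the circle exactly at the published
# genome lengths (17116 / 17182 / 17235 / 17219 bp).
name	role	strand	HB_len	HB_ig	HB_start	HB_stop	JB_len	JB_ig	JB_start	JB_stop	RB_len	RB_ig	RB_start	RB_stop	WB_len	WB_ig	WB_start	WB_stop
tRNA-Phe	tRNA	H	69	0			70	0			70	0			69	0
12SrRNA	rRNA	H	979	0			979	0			980	0			979	0
tRNA-Val	tRNA	H	70	0			70	0			70	0			70	0
16SrRNA	rRNA	H	1602	0			1604	0			1605	0			1603	0
tRNA-Leu(UUR)	tRNA	H	77	0			77	0			77	0			77	0
NAD1	PCG	H	971	0	ATG	TAG	971	0	ATG	TAG	971	0	ATG	TAG	971	0	ATG	TAG
tRNA-Ile	tRNA	H	70	-1			70	-1			70	-1			70	-1
tRNA-Gln	tRNA	L	71	9			71	9			71	9			71	9
tRNA-Met	tRNA	H	69	0			69	0			69	0			69	0
NAD2	PCG	H	1039	0	ATG	TAG	1039	0	ATG	TAG	1039	0	ATG	TAG	1039	0	ATG	TAG
tRNA-Trp	tRNA	H	73	11			73	11			73	11			73	11
tRNA-Ala	tRNA	L	69	1			69	1			69	1			69	1
tRNA-Asn	tRNA	L	74	-1			74	-1			74	-1			74	-1
OL	OL	H	34	-2			34	-2			34	-2			34	-2
tRNA-Cys	tRNA	L	65	0			65	0			65	0			65	0
tRNA-Tyr	tRNA	L	66	1			66	1			66	1			66	1
COX1	PCG	H	1545	-5	GTG	AGA	1545	-5	GTG	AGA	1545	-5	GTG	AGA	1545	-5	GTG	AGA
tRNA-Ser(UCN)	tRNA	L	71	1			71	1			71	1			71	1
tRNA-Asp	tRNA	H	69	0			69	0			69	0			69	0
COX2	PCG	H	687	1	ATG	TAA	687	1	ATG	TAA	687	1	ATG	TAA	687	1	ATG	TAA
tRNA-Lys	tRNA	H	73	1			73	1			73	1			73	1
ATP8	PCG	H	165	-10	ATG	TAA	165	-10	ATG	TAA	165	-10	ATG	TAA	165	-10	ATG	TAA
ATP6	PCG	H	683	0	ATG	TAA	683	0	ATG	TAA	683	0	ATG	TAA	683	0	ATG	TAA
COX3	PCG	H	784	0	ATG	T	784	0	ATG	T	784	0	ATG	T	784	0	ATG	T
tRNA-Gly	tRNA	H	70	0			70	0			70	0			70	0
NAD3	PCG	H	352	-2	ATG	TAG	350	0	ATG	T	350	0	ATG	T	350	0	ATG	TAG
tRNA-Arg	tRNA	H	70	0			70	0			71	0			70	0
NAD4L	PCG	H	297	-7	ATG	TAA	297	-7	ATG	TAA	297	-7	ATG	TAA	297	-7	ATG	TAA
NAD4	PCG	H	1381	0	ATG	T	1381	0	ATG	T	1381	0	ATG	T	1381	0	ATG	T
tRNA-His	tRNA	H	70	0			70	0			70	0			70	0
tRNA-Ser(AGY)	tRNA	H	62	-1			62	-1			62	-1			62	-1
tRNA-Leu(CUN)	tRNA	H	74	0			74	0			74	0			74	0
NAD5	PCG	H	1779	-5	ATG	TAA	1779	-5	ATG	TAA	1779	-5	ATG	TAA	1779	-5	ATG	TAA
NAD6	PCG	L	525	0	ATG	AGG	525	0	ATG	AGG	525	0	ATG	AGG	525	0	ATG	AGG
tRNA-Glu	tRNA	L	68	3			68	3			68	3			68	3
Cytb	PCG	H	1140	3	ATG	TAA	1140	3	ATG	TAA	1140	3	ATG	TAA	1140	3	ATG	TAA
tRNA-Thr	tRNA	H	74	14			74	14			74	13			74	14
tRNA-Pro	tRNA	L	71	0			71	0			71	0			71	0
D-loop	control_region	H	1597	0			1660	0			1711	0			1699	0
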