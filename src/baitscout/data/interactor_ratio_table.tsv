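# Ranked bait/control (NTAL/CT) iBAQ ratio table for the 49 selected interactors,
# one row per protein, per-cell-line ratios for NB4 and U937.
# Transcription note: the typeset source concatenates rank and ratio digits; the
# COX5B row admits two digit groupings (nb4=1396.17/u937=1.9 vs nb4=1396.1/u937=71.9).
# The grouping consistent with the dual-cell-line ">30-fold" selection criterion
# (1396.1 / 71.9) is adopted here.
rank	protein_accession	gene_symbol	ratio_nb4	ratio_u937
1	P13987	CD59	11003.31	65.79
2	P63218	GNG5	8234.27	3375.9
3	O43504	LAMTOR5	7832.41	417.52
4	Q6IAA8	LAMTOR1	7359.82	195.24
5	Q9Y6H1	CHCHD2	5420.04	584.03
6	P49795	RGS19	5149.09	1959.82
7	O60262	GNG7	4588.96	3036.13
8	Q9Y2Q5	LAMTOR2	4507.38	59.02
9	Q9UHA4	LAMTOR3	3491.67	170.53
10	Q14699	RFTN1	2865.07	1337.46
11	O60232	ZNRD2	2363.64	2000.01
12	Q10589	BST2	2207.63	465.4
13	Q9NWQ8	PAG	1932.26	1251.04
14	P10606	COX5B	1396.1	71.9
15	P41240	CSK	1391.21	947.27
16	P29966	MARCKS	1304.47	643.21
17	P16070	CD44	768.65	1810.18
18	O75695	RP2	620.41	280.05
19	P04156	PRNP	605.57	213.25
20	Q9GZY6	LAT2	601.91	23203.65
21	Q9P0J0	NDUFA13	560.22	31.04
22	Q9BTV4	TMEM43	558.34	30.56
23	Q96BS2	TESC	547.81	130.58
24	P37235	HPCAL1	547.8	283.07
25	O75955	FLOT1	401.21	381.53
26	P59768	GNG2	196.72	4926.98
27	Q02218	OGDH	131.05	87.76
28	Q96B97	SH3KBP1	126.09	147.21
29	P51665	PSMD7	124.02	484.03
30	E9PAV3	NACA	107.67	37.21
31	Q32MZ4	LRRFIP1	90.86	212.84
32	P07948	LYN	75.97	2664.86
33	P09382	LGALS1	75.23	68.21
34	O00182	LGALS9	74.99	19304.74
35	P35232	PHB	73.81	1119.05
36	P62993	GRB2	50.54	170.66
37	Q3ZCQ8	TIMM50	47.56	164.48
38	P08631	HCK	43.81	1414.6
39	P08754	GNAI3	41.11	4540.08
40	Q99623	PHB2	40.77	1174.56
41	P04899	GNAI2	37.68	479.24
42	Q9UJZ1	STOML2	37.29	37.06
43	P06241	FYN	36.63	764.61
44	P50151	GNG10	35.11	2135.77
45	Q92835	INPP5D	33.69	1315.36
46	Q86WV6	STING1	32.51	788.15
47	P46459	NSF	32.17	103.61
48	O94905	ERLIN2	30.54	1786.4
49	Q14254	FLOT2	30.45	1008.94
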