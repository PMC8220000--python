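# Per-gene log2 expression medians in healthy bone-marrow HSCs (n=6) versus AML
# blasts (n=198) with the published two-group p-value, for the bait (NTAL) and
# its interactor genes. One row per gene as printed in the source table (50 rows;
# the printed table includes YES and GNB1 alongside the ranked interactor symbols).
# The printed significance-legend inequality signs are inverted in the source;
# starred entries correspond to p < 0.05 and the numeric p-values below are
# authoritative.
gene_symbol	hsc_median	aml_median	p_value
NTAL	7.43	7.55	0.105
LAMTOR5	9.2	9.84	0.006
LAMTOR1	7.85	8.5	0.051
LAMTOR2	6.68	8.09	0.0042
LAMTOR3	5.42	4.34	0.0001
LYN	10.15	10.2	0.460
CD44	10.3	12.1	0.003
HCK	3.5	7.5	0.001
INPP5D	9	7.98	0.029
YES	8.43	6.21	0.001
GNG5	8.5	10.28	0.001
CHCHD2	9.26	10.68	0.002
CD59	10.33	6.35	0.0001
GNG10	104	69.9	0.054
NACA	13.4	13.2	0.001
RGS19	7.47	8.53	0.0007
RFTN1	5.64	5.32	0.642
BST2	9.2	7.07	0.002
GNG2	5.16	7.87	0.001
GNAI3	8.9	9.77	0.043
PAG1	3.5	7.35	0.001
CSK	8.2	8.25	0.862
COX5B	8.77	10.05	0.0024
MARCKS	4.99	8.26	0.0085
RP2	4.62	6.001	0.0001
SSSCA1	6.35	7.12	0.071
TESC	4.87	7.01	0.001
GRB2	8.5	8.85	0.072
PHB	8.26	8.12	0.359
GNG7	6.2	6.32	0.667
LGALS9	6.5	7.25	0.029
LGALS1	4.48	10.12	0.001
ERLIN2	7.03	7.01	0.793
FLOT1	7.4	8.64	0.020
FLOT2	6.75	6.95	0.170
HPCAL1	6.3	6.2	0.617
PHB2	10.02	10.05	0.974
GNAI2	8.4	10.05	0.003
PRNP	6.2	7.9	0.001
NDUFA13	7.6	9.3	0.0054
TMEM43	8.31	8.29	0.843
OGDH	5.8	6.18	0.134
GNB1	8.36	9.95	0.004
SH3KBP1	7.85	8.38	0.0337
TMEM173	8.95	8.66	0.872
PSMD7	8.44	8.25	0.3612
LRRFIP1	11.49	10.73	0.0075
TIMM50	6.15	6.81	0.0677
STOML2	7.44	7.98	0.2702
NSF	6.31	5.94	0.0735
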