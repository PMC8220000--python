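# Reported xenograft tumor-mass group summaries (grams): control (CT) versus
# bait-knockdown (KD) grafts for each cell line. Used for the worked fold-change
# example.
cell_line	group	mean_g	sd_g	n
U937	CT	1.073	0.1486	4
U937	KD	0.5975	0.1506	4
NB4	CT	1.286	0.3137	5
NB4	KD	0.8540	0.3402	5
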