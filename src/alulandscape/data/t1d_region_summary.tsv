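category	n_sequences	total_length_nt	gc_pct	n_repeats	n_alus	pct_seq_with_repeats	pct_seq_with_alus	pct_covered_by_alus
genes	941	20074601	44.54	37101	11335	81.08	59.29	15.03
cds	2419	2568639	55.81	660	56	20.95	1.77	0.17
introns	2403	64787126	43.65	125952	40990	92.09	80.44	16.53
utr5	2048	491916	59.87	582	68	20.41	3	1.83
utr3	1758	1287596	48.10	1025	217	30.48	8.02	3.88
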