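region	n_sense	n_antisense
t1d_utr5	17	51
t1d_utr3	112	105
human_utr5	681	2028
human_utr3	6075	5867
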