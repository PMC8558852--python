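category	biotype	direction	size_a	size_b	shared
mrna_up	mRNA	up	702	600	489
mrna_down	mRNA	down	1717	1696	1504
lncrna_up	lncRNA	up	708	593	472
lncrna_down	lncRNA	down	855	711	634
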