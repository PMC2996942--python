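# sigma32 target candidates not present in the earlier ChIP-chip screen
# (1-based genomic position, locus name, ChIP signal)
position	name	chip_signal
354094	codB	1.9
1660133	ynfF	0.5
1666656	dgsA	1.5
1798225	rpmI	0.5
2276466	yejG	0.6
4148429	ppc	0.8
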