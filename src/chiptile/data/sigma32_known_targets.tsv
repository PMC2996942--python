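# Previously described sigma32 target sites on the E. coli chromosome
# (1-based genomic position, locus name, ChIP signal where redetected; '-' = not redetected)
position	name	chip_signal
12153	dnaK	2.9
63524	hepA	1.1
231081	yafD	1.2
415363	sbcD	1.3
455839	clpP	2.0
458088	lon	2.5
494367	htpG	2.8
517509	ybbN	2.2
661879	ybeD	2.4
692735	ybeZ	2.5
921161	macB	2.1
1027921	yccV	2.0
1120264	yceP	2.1
1173268	mfd	-
1189625	phoP	-
1329105	topA	2.4
1338173	yciS	2.1
1382156	ycjX	2.9
1441543	ldhA	-
1744259	ydhQ	1.4
1860640	gapA	2.1
1910677	htpX	1.6
2732265	clpB	2.2
2748779	grpE	2.3
2925909	sdaC	1.1
3210766	rpoD	1.7
3325757	ftsJ	2.2
3437596	yhdN	1.3
3472778	rpsL	2.3
3527175	yrfG	2.7
3643241	prlC	2.4
3865515	ibpA	2.4
3878830	recF	-
4120359	hslV	2.5
4366663	fxsA	2.4
4368634	groE	2.2
4397495	miaA	2.1
4429090	cycA	0.6
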