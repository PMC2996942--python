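# sigma32 target sites reported only by the earlier ChIP-chip screen
# (1-based genomic position, locus name, ChIP signal where redetected; '-' = not redetected)
position	name	chip_signal
22199	ileS	-
239254	yafU	1.6
516521	ybbM	-
705196	glnS	-
918375	ybjX	-
1063460	yccE	-
1213931	ycgF	-
1247539	dhaM	-
1293531	tdk/ychG	-
1579583	ydeN	-
1581861	ydeO	-
1584068	ydeP	-
1609353	yneF	-
1624219	dcp	-
1710454	ydgR	-
1789863	ydiV	-
1894985	sdaA	0.7
2166182	yegR	-
2209265	yehR	-
2217821	yehZ	-
2236301	mglA	-
2288414	narP	-
2319337	atoS	-
2385514	yfbM/yfbN	1.0
2520600	xapR	-
2533473	crr	-
2735126	yfiO	-
2762841	yfjL	-
2764390	yfjN	-
2769847	yfjU	0.9
2771222	b2641	-
2780322	ypjA	1.3
2798757	nrdH	-
2879078	ygcI	-
2923838	yqcD	-
3117399	yghJ	-
3427148	yrdA	-
3543459	yhgH	-
3725552	yiaA	-
3764283	yibA	-
3766465	yibG	-
4124864	rpmE	-
4359431	cadC	-
4435901	ytfI	-
4465355	treR	-
4482322	holC	-
4524170	yjhI	1.2
4539344	fimB	0.8
4570170	yjiT	-
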