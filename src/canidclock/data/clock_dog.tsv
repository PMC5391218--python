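# assembly=canFam3	intercept=-6.9009	age_transform=log_e
chrom	pos	coef	mean_meth	age_corr	human_chrom	human_pos	proximal_genes
chr1	98804509	-0.1771	0.92	-0.56	chr9	95371248	ECM2 (-72912), IPPK (+61298)
chr2	34467253	-0.1762	0.96	-0.52	chr10	323319	Intergenic
chr2	50165769	1.8403	0.97	0.56	chr5	63460330	RNF180 (-1378)
chr3	54128482	0.1444	0.77	0.51	chr15	85429683	PDE8A, (-93987), SLC28A1 (+1771)
chr4	28320267	-0.4038	0.94	-0.43	chr10	80292869	Intergenic
chr5	19204758	-0.5393	0.31	-0.62	chr11	114000061	ZBTB16 (+69747)
chr5	32946701	0.1414	0.63	0.67	chr17	8027247	ALOXE3, (-4883), HES7 (+154)
chr5	57889544	0.1104	0.88	0.45	chr1	3202081	Intergenic
chr6	31347568	-0.0245	0.64	-0.5	chr16	11536754	ENSG00000188897 (+80689), RMI2 (+97467)
chr6	77030251	0.5807	0.82	0.6	chr1	68732333	WLS, (-34106)
chr7	54060517	0.3047	0.06	0.48	chr18	33708261	ELP2 (-1599), SLC39A6 (+1019)
chr8	50434546	0.0351	0.91	0.42	chr14	78126349	SPTLC2 (-43234), ALKBH1 (+48013)
chr9	58841067	0.318	0.15	0.61	chr9	126779366	LHX2 (+5478)
chr10	21355951	0.3876	0.86	0.52			
chr10	55453590	-0.4182	0.95	-0.75	chr2	54776879	SPTBN1 (+93458)
chr10	56694481	0.4854	0.09	0.46	chr2	56151248	EFEMP1 (+25)
chr10	62832468	0.2077	0.77	0.6	chr2	63279783	OTX1 (+1847)
chr10	62832512	0.2347	0.58	0.67	chr2	63279827	OTX1 (+1891)
chr11	4422863	0.7296	0.91	0.44	chr5	113831979	Intergenic
chr11	56812470	0.0579	0.87	0.47	chr9	102590004	NR4A3 (+996)
chr11	68812130	1.204	0.95	0.5	chr9	117441733	C9orf91 (+68248)
chr12	67228192	1.4284	0.98	0.39	chr6	110931985	Intergenic
chr12	67482078	-0.2241	0.19	-0.53	chr6	111267687	GTF3C6 (-12075), AMD1 (+71715)
chr12	67482081	-0.0314	0.26	-0.48	chr6	111267690	GTF3C6 (-12072), AMD1 (+71718)
chr12	71716109	0.0065	0.82	0.34			
chr14	8324605	0.3087	0.65	0.59	chr7	127670876	LRRC4 (+246)
chr14	34373167	0.2091	0.76	0.64	chr7	20371740	ITGB8 (+995)
chr18	36757482	-0.403	0.83	-0.63	chr11	30565405	MPPED2 (+36637)
chr19	22964392	-0.0157	0.89	-0.54	chr2	128408298	GPR17 (+4860), LIMS2 (+13821)
chr20	43010636	0.4045	0.97	0.5			
chr20	44455198	0.0664	0.72	0.47			
chr20	56821233	1.2199	0.98	0.42	chr19	2210771	SF3A2 (-25748), DOT1L (+46624)
chr22	49950553	0.1423	0.54	0.63	chr13	100636088	ZIC2 (+2063)
chr24	37978456	-0.0979	0.77	-0.59			
chr28	39644410	0.0856	0.84	0.37			
chr30	38620897	1.4441	0.94	0.51	chr15	78043186	Intergenic
chr31	37492782	-0.0028	0.47	-0.51			
chr33	23073877	-0.0296	0.96	-0.52	chr3	119134135	TMEM39A (+48393)
chr34	40999085	-0.1395	0.97	-0.46	chr3	177284378	Intergenic
chr36	2545142	0.432	0.5	0.62	chr2	157179848	NR4A2 (+9379)
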