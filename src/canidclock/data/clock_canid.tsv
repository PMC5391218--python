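# assembly=canFam3	intercept=4.382	age_transform=log_e
chrom	pos	coef	mean_meth	age_corr	human_chrom	human_pos	proximal_genes
chr1	815007	-0.405	0.95	-0.27	chr18	77637184	KCNG2 (+13517), PQLC1 (+74479)
chr1	48720985	0.5191	0.95	0.31			
chr1	49472858	0.2594	0.64	0.28			
chr1	90590933	-0.0041	0.94	-0.32	chr9	1872401	Intergenic
chr1	98573761	-0.0837	0.6	-0.42			
chr1	98573781	-0.1991	0.2	-0.37			
chr1	101051499	-0.2786	0.79	-0.4	chr19	57398441	ZIM2 (-46345)
chr1	108136920	0.933	0.98	0.22	chr19	48626542	PLA2G4C (-12469), LIG1 (+47317)
chr1	117122008	-0.2091	0.82	-0.33	chr19	36035408	TMEM147 (-1088)
chr1	117495962	-0.1664	0.86	-0.41	chr19	35540744	FXYD3 (-66421), HPN (+9335)
chr1	121791246	-0.3188	0.67	-0.38	chr19	30153492	PLEKHF1 (-2470)
chr1	121796139	0.3134	0.96	0.28			
chr1	121864927	0.3367	0.83	0.3	chr19	30042558	POP4 (-52365), VSTM2B (+25153)
chr2	10101121	-0.0266	0.65	-0.29			
chr2	30853505	-0.0048	0.93	-0.28	chr10	4714389	Intergenic
chr2	36347652	0.0248	0.37	0.36	chr5	140749805	PCDHGA6 (-3845), PCDHGB3 (-25)
chr2	71080824	0.0288	0.86	0.33	chr1	30051475	Intergenic
chr2	82210243	-0.387	0.94	-0.22	chr1	15602565	Intergenic
chr2	84377388	-0.4829	0.97	-0.36	chr1	11951757	NPPB (-32770), KIAA2013 (+34722)
chr2	84445018	0.0924	0.26	0.33	chr1	11864680	CLCN6 (-1587), MTHFR (-1379)
chr3	1128258	-0.0993	0.94	-0.37			
chr3	51442070	-0.0641	0.8	-0.3	chr15	88733456	NTRK3 (+66204)
chr3	60468935	-0.2449	0.82	-0.43	chr4	8834358	HMX1 (+39184)
chr3	62880832	0.4931	0.88	0.25	chr4	17638199	MED28 (+21946)
chr3	84450199	-0.0696	0.89	-0.49	chr4	25978965	SMIM20 (+63140)
chr4	28034141	-0.6356	0.14	-0.33	chr10	79971431	Intergenic
chr4	28162022	-0.1129	0.89	-0.32	chr10	80116134	Intergenic
chr4	28489863	0.0289	0.7	0.24	chr10	80479452	Intergenic
chr4	79153238	0.1058	0.09	0.42	chr5	27038840	CDH9 (-148)
chr5	4750111	-0.089	0.35	-0.5	chr11	129969307	ST14 (-60149), APLP2 (+29507)
chr14	41413362	-0.2829	0.57	-0.33	chr7	28355716	CREB5 (-96427)
chr14	59995975	-0.0142	0.73	-0.34	chr7	121776852	AASS (-2977)
chr15	17780647	1.3988	0.97	0.29	chr14	20915434	TEP1 (-33855), OSGEP (+7829)
chr15	17785631	-0.3897	0.94	-0.43	chr14	20921454	APEX1 (-1899), OSGEP (+1809)
chr16	131577	-0.0629	0.73	-0.31			
chr16	247019	0.8011	0.83	0.34			
chr17	18033866	0.2802	0.82	0.32	chr2	23704553	Intergenic
chr18	1791242	-0.0118	0.94	-0.35	chr7	50515762	FIGNL1 (+1659)
chr18	25850449	-0.2607	0.92	-0.34			
chr18	33813035	-0.1549	0.78	-0.41	chr11	33962891	LMO2 (-49056)
chr18	43740411	-0.1646	0.94	-0.34	chr11	45669463	CHST1 (+17708)
chr18	48905778	0.0765	0.72	0.41	chr11	68925723	Intergenic
chr18	49633631	-0.0336	0.49	-0.22	chr11	67984189	SUV420H1 (-3308)
chr18	53920336	-0.0957	0.8	-0.4			
chr20	44455198	0.3338	0.72	0.46			
chr20	49366316	-0.0004	0.71	-0.28	chr19	12895268	HOOK2 (-8932), JUNB (-7041)
chr21	23088752	-0.4109	0.88	-0.28	chr11	75219103	GDPD5 (+17844)
chr21	47917499	-0.0235	0.84	-0.29	chr11	27349807	Intergenic
chr22	56299850	-0.2509	0.89	-0.32	chr13	108022629	Intergenic
chr23	24782165	-0.1049	0.89	-0.33	chr3	18277027	Intergenic
chr23	24782179	-0.658	0.94	-0.31	chr3	18277013	Intergenic
chr24	42551119	-0.2892	0.93	-0.35	chr20	56148739	PCK1 (+12604), ZBP1 (+46789)
chr24	45589901	0.2135	0.97	0.27	chr20	59877087	CDH4 (+49606)
chr26	220859	0.0037	0.98	0.27			
chr26	5991914	-0.2154	0.93	-0.37	chr12	124138408	TCTN2 (-17251), GTF2H3 (+20033)
chr26	11457252	-0.3679	0.94	-0.28	chr12	114784708	TBX5 (+61538)
chr26	37645878	-0.4125	0.93	-0.3			
chr27	1189935	-0.0497	0.78	-0.39	chr12	54471815	HOXC4 (+24155)
chr27	2886690	-0.0004	0.86	-0.44	chr12	52559286	KRT80 (+26497), C12orf44 (+95532)
chr27	45394279	-0.4689	0.93	-0.45			
chr28	23823079	-0.2956	0.91	-0.31			
chr28	40564054	-0.0603	0.96	-0.33	chr10	134593678	NKX6-2 (+5877)
chr30	15275091	-0.0557	0.89	-0.31			
chr30	27934524	-0.0484	0.93	-0.26	chr15	63648005	CA12 (+26354), APH1B (+78253)
chr30	38620897	0.8567	0.94	0.33	chr15	78043186	Intergenic
chr31	27720671	0.0332	0.16	0.46	chr21	34444104	OLIG1, (+1655)
chr31	36955453	-0.5267	0.91	-0.36	chr21	44079991	PDE9A (+6127)
chr31	37492782	-0.4942	0.49	-0.56			
chr32	1431916	-0.2835	0.07	-0.3	chr4	77752402	Intergenic
chr32	38110814	-0.076	0.87	-0.35			
chr33	22992599	-0.0003	0.93	-0.34	chr3	119042586	ARHGAP31 (+29367)
chr33	25783582	0.3819	0.98	0.34	chr3	122422615	PARP14 (+23151), HSPBAP1 (+90055)
chr33	31142995	-0.8311	0.95	-0.3	chr3	194291430	ATP13A3 (-72338), TMEM44 (+62719)
chr34	40858941	-0.1582	0.93	-0.38	chr3	177096996	Intergenic
chr35	2307155	-0.1171	0.94	-0.32	chr6	1886203	Intergenic
chr36	2545193	0.2403	0.84	0.47	chr2	157179898	NR4A2 (+9329)
chr36	19969591	0.0515	0.27	0.38	chr2	177025691	HOXD1 (-27615), HOXD4 (+9742)
chr37	6301	-0.1058	0.69	-0.43			
chr37	25454687	0.4555	0.32	0.33	chr2	219736500	WNT10A (-8584), WNT6 (+11957)
chr38	16230281	0.1055	0.92	0.23	chr1	221912099	DUSP10 (+3418)
chr38	22365525	-0.1451	0.89	-0.36	chr1	159724037	CRP (-39659), DUSP23 (-26755)
chr38	22792877	0.7599	0.72	0.43	chr1	159145579	DARC (-29621), CADM3 (+4181)
chrX	80013740	-0.133	0.85	-0.29			
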