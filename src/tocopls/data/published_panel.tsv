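snp_id	gene	alleles	alt_freq	region	model	beta	se	p	reg_score
rs709158	PPARG	A>G	0.35	intron	additive	52.5	14.3	0.0007	0.61
rs1151996	PPARG	C>A	0.62	intron	additive	52.6	15.2	0.0013	0.44
rs3211958	CD36	A>G	0.45	intron	additive	49.7	16.0	0.0033	0.13
rs2921193	PPARG	G>A	0.47	intron	additive	41.8	14.0	0.0048	0.18
rs2575876	ABCA1	G>A	0.26	intron	additive	45.3	15.5	0.0057	0.61
rs709150	PPARG	C>G	0.39	intron	additive	41.4	14.4	0.0064	0.61
rs4739050	TTPA	A>G	0.39	intergenic	additive	-43.7	15.6	0.0078	0.18
rs1152002	PPARG	C>T	0.48	intron	additive	39.8	15.5	0.0143	0.61
rs1151998	PPARG	A>G	0.47	intron	additive	36.2	14.4	0.0157	0.61
rs7951761	BUD13	G>A	0.50	intergenic	additive	39.9	16.3	0.0186	0.13
rs2777788	ABCA1	A>G	0.39	intron	additive	36.0	15.8	0.0275	0.61
rs6472073	TTPA	C>A	0.48	intergenic	additive	31.6	14.0	0.0295	0.59
rs2297406	ABCA1	C>T	0.30	intron	additive	34.5	15.5	0.0312	0.00
rs4823164	PNPLA3	C>T	0.46	intergenic	additive	34.2	15.9	0.0372	0.38
rs10891938	BUD13	G>A	0.37	intergenic	additive	31.0	15.0	0.0453	0.59
rs2280434	CYP4F2	C>A	0.45	3'UTR	additive	30.2	14.7	0.0468	0.51
rs573126	BUD13	A>C	0.32	intergenic	additive	34.0	16.8	0.0491	0.13
rs11216029	BUD13	G>T	0.42	intergenic	additive	-33.2	16.4	0.0498	0.13
rs709157	PPARG	G>A	0.31	intron	dominant	37.1	10.1	0.0007	0.55
rs1561166	ABCA1	T>C	0.09	intergenic	dominant	56.9	15.6	0.0008	0.13
rs1783225	BUD13	T>C	0.11	intergenic	dominant	39.2	11.4	0.0013	0.91
rs12686004	ABCA1	G>A	0.12	intergenic	dominant	42.7	12.5	0.0015	0.59
rs1648364	BUD13	T>C	0.13	intergenic	dominant	42.5	12.5	0.0016	0.13
rs2275542	ABCA1	C>T	0.32	intron	dominant	-34.3	10.4	0.0021	0.85
rs4743764	ABCA1	T>C	0.42	intron	dominant	-34.8	10.9	0.0027	0.61
rs13076933	PPARG	T>G	0.26	2kb_upstream	dominant	32.9	10.5	0.0032	0.24
rs3773161	MGLL	T>C	0.03	intron	dominant	49.6	16.2	0.0039	0.69
rs12271395	BUD13	A>C	0.17	intergenic	dominant	32.7	10.9	0.0044	0.13
rs6778770	MGLL	A>G	0.23	intron	dominant	29.9	10.7	0.0079	0.51
rs4475472	TTPA	T>C	0.08	intergenic	dominant	42.7	15.3	0.0079	0.04
rs6008798	PPARA	T>C	0.27	intergenic	dominant	-29.6	10.7	0.0086	0.61
rs482795	BUD13	A>G	0.26	intergenic	dominant	32.6	11.9	0.0088	0.13
rs13288647	PLIN2	A>G	0.32	intergenic	dominant	-29.4	10.8	0.0094	0.00
rs670345	DGAT2	G>A	0.07	intergenic	dominant	-36.1	13.7	0.0120	0.61
rs608318	MGLL	T>G	0.14	intron	dominant	-30.4	11.7	0.0131	0.61
rs9289316	MGLL	A>G	0.11	intron	dominant	43.3	16.7	0.0132	0.61
rs12629751	PPARG	C>T	0.09	intron	dominant	43.1	16.7	0.0136	0.18
rs3904998	ABCA1	T>C	0.21	intron	dominant	28.7	11.1	0.0137	0.13
rs135549	PPARA	T>C	0.42	intron	dominant	-29.7	11.7	0.0153	0.72
rs2622621	ABCG2	C>G	0.27	intron	dominant	27.4	10.9	0.0157	0.61
rs135552	PPARA	T>C	0.27	intron	dominant	-27.8	11.1	0.0165	0.33
rs2074303	TM6SF2	C>T	0.34	intron	dominant	28.5	11.5	0.0180	0.61
rs519000	BUD13	C>T	0.16	intergenic	dominant	28.4	11.6	0.0184	0.61
rs11716997	MGLL	T>G	0.43	intergenic	dominant	-31.4	12.8	0.0185	0.36
rs1152001	PPARG	A>G	0.21	intron	dominant	-26.0	11.2	0.0249	0.61
rs4922131	LPL	G>A	0.44	intergenic	dominant	28.2	12.1	0.0252	0.55
rs1383194	NKAIN3	T>C	0.30	intron	dominant	26.8	11.5	0.0252	0.18
rs13270035	NKAIN3	A>G	0.16	intergenic	dominant	-25.7	11.2	0.0268	0.13
rs4149275	ABCA1	A>G	0.18	intron	dominant	27.9	12.2	0.0272	0.13
rs3934667	SF4	G>T	0.35	2kb_upstream	dominant	27.1	11.9	0.0282	0.98
rs929090	PNPLA3	A>G	0.47	intergenic	dominant	27.0	11.9	0.0288	0.13
rs2886571	CYP4F2	T>C	0.25	intron	dominant	-25.9	11.4	0.0290	0.18
rs7652615	MGLL	T>G	0.16	intron	dominant	-26.7	11.9	0.0304	0.52
rs1563325	NKAIN3	G>A	0.18	intron	dominant	24.8	11.1	0.0307	0.61
rs11204094	LPL	A>G	0.43	intergenic	dominant	-24.6	11.0	0.0309	0.27
rs1152004	PPARG	A>G	0.21	intergenic	dominant	25.2	11.4	0.0323	0.61
rs11605293	BUD13	C>T	0.09	intergenic	dominant	-27.0	12.2	0.0326	0.13
rs17193714	NKAIN3	C>T	0.09	intergenic	dominant	-31.1	14.0	0.0327	0.13
rs7651814	MGLL	C>T	0.16	intron	dominant	-26.2	11.9	0.0340	0.98
rs4646437	CYP3A4	G>A	0.11	intron	dominant	-26.6	12.2	0.0358	0.93
rs2174876	BUD13	G>A	0.46	intergenic	dominant	-25.3	11.7	0.0373	0.13
rs9919066	ABCA1	C>T	0.09	intergenic	dominant	-27.9	13.0	0.0380	0.00
rs3219281	NR1H2	C>T	0.09	0.5kb_downstream	dominant	-33.9	15.8	0.0383	0.39
rs2074296	TM6SF2	A>G	0.33	intergenic	dominant	25.1	11.8	0.0389	0.67
rs1350057	NKAIN3	C>T	0.11	intron	dominant	26.8	12.6	0.0396	0.18
rs11215905	BUD13	T>C	0.45	intergenic	dominant	-24.9	11.7	0.0401	0.00
rs4823153	PNPLA3	T>C	0.23	intergenic	dominant	-23.4	11.1	0.0414	0.61
rs2740486	ABCA1	T>G	0.47	intron	dominant	26.5	12.6	0.0421	0.51
rs4425750	NKAIN3	C>T	0.11	intron	dominant	26.4	12.6	0.0424	0.55
rs479504	MGLL	C>A	0.21	intron	dominant	25.6	12.3	0.0439	0.76
rs6439099	MGLL	T>C	0.08	intergenic	dominant	-31.0	14.9	0.0439	0.18
rs3124016	ABCA1	G>A	0.26	intergenic	dominant	23.4	11.3	0.0453	0.11
rs573713	BUD13	A>G	0.13	intergenic	dominant	-23.8	11.6	0.0466	0.13
rs11216157	APOA1	A>G	0.13	intron	dominant	-23.7	11.6	0.0472	0.70
rs10991509	ABCA1	A>G	0.28	intergenic	dominant	-23.4	11.4	0.0476	0.61
rs11216026	BUD13	A>G	0.28	intergenic	dominant	-22.6	11.1	0.0484	0.13
rs11215728	BUD13	C>T	0.40	intergenic	dominant	-23.3	11.5	0.0490	0.61
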