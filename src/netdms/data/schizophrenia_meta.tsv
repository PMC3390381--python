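snp_id	genes	chrom	pos	allele	p_meta	beta	se	p_gain	p_nongain	p_isc	p_het
rs9272219	HLA-DQA1	6	32710247	T/G	1.46e-6	-0.15	0.03	0.06	0.06	1.58e-5	0.76
rs10244946	MAD1L1	7	1887594	A/G	4.30e-6	-0.16	0.03	1.81e-4	0.18	2.36e-3	0.27
rs3778994	MAD1L1	7	2142381	A/C	6.79e-6	-0.15	0.03	4.54e-4	0.61	1.20e-4	0.07
rs10275045	MAD1L1	7	1887352	T/C	9.79e-6	-0.13	0.03	1.44e-4	0.20	3.61e-3	0.16
rs4721190	MAD1L1	7	1921258	A/G	1.39e-5	-0.15	0.03	3.07e-4	0.17	6.42e-3	0.32
rs2056480	MAD1L1	7	1920827	A/G	1.44e-5	-0.12	0.03	4.15e-5	0.31	5.69e-3	0.07
rs9272535	HLA-DQA1	6	32714734	A/G	1.58e-5	-0.16	0.04	0.07	0.07	8.27e-5	0.41
rs3132649	RPP21,TRIM39	6	30429036	A/G	1.64e-5	-0.20	0.05	0.01	0.46	6.46e-7	0.00
rs10224497	MAD1L1	7	2116493	G/A	1.75e-5	-0.14	0.03	4.32e-5	0.91	8.46e-4	0.02
rs741326	CD207,CLEC4F	2	70912343	G/A	2.65e-5	-0.12	0.03	0.31	0.09	4.14e-5	0.46
rs12646184	SMARCAD1	4	95402239	T/C	3.21e-5	0.12	0.03	2.85e-5	0.11	0.03	0.05
rs2071278	AGER,NOTCH4	6	32273422	G/A	3.23e-5	-0.16	0.04	0.10	0.98	2.78e-6	0.06
rs2664871	SMARCAD1	4	95365304	T/C	4.69e-5	0.12	0.03	3.89e-5	0.12	0.04	0.05
rs172531	RERE	1	8418177	G/A	5.62e-5	0.12	0.03	0.01	0.75	4.03e-5	0.06
rs2087170	SMARCAD1	4	95381983	G/T	5.83e-5	0.14	0.03	5.59e-5	0.10	0.12	0.11
rs3757440	MAD1L1	7	2239462	G/A	6.01e-5	-0.14	0.04	6.41e-4	0.56	2.35e-3	0.14
rs301791	RERE	1	8390959	T/A	6.45e-5	0.12	0.03	4.88e-3	0.78	9.90e-5	0.06
rs301801	RERE	1	8418532	C/T	6.66e-5	0.12	0.03	0.01	0.73	4.51e-5	0.06
rs302719	RERE	1	8412907	G/T	7.01e-5	0.12	0.03	0.01	0.73	4.84e-5	0.06
rs349171	PTPRG	3	62026751	T/C	9.39e-5	-0.16	0.04	0.50	0.08	9.58e-5	0.35
rs8336	SMARCAD1	4	95430633	T/C	9.81e-5	-0.13	0.03	1.43e-3	0.18	0.02	0.47
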