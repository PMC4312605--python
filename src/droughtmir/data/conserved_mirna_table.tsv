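mirna_id	homolog	tpm_c1	tpm_t1	tpm_c2	tpm_t2	log2_g1	log2_g2	pattern	target
tae-miR156k	gma-miR156k	0.25	1.71	0.19	5194.72	2.77	14.75	up_both	SBP
tae-miR159a-5p	gma-miR159a-5p	0.17	1.61	1.04	133.40	3.27	7.01	up_both	Serine/arginine repetitive matrix 1
tae-miR166l-5p	osa-miR166l-5p	0.92	33.48	0.01	1.62	5.19	7.34	up_both	FAM10 family protein
tae-miR166n-5p	osa-miR166n-5p	0.58	38.03	0.01	1.28	6.03	7.00	up_both
tae-miR167b	sof-miR167b	0.42	15.74	1.60	233.55	5.24	7.19	up_both
tae-miR168a-5p	zma-miR168a-5p	5.75	556.21	1.79	46.92	6.60	4.71	up_both
tae-miR168b	sof-miR168b	3.66	16.60	2.45	220.22	2.18	6.49	up_both	Short-chain dehydrogenase/reductase
tae-miR444c.1	osa-miR444c.1	4.83	23.99	38.79	8.02	2.31	1.34	up_both	MADS-box transcription factor
tae-miR827b	osa-miR827b	0.25	0.76	0.28	204.50	1.60	9.50	up_both	ATP-dependent Clp protease
tae-miR829-3p	aly-miR829-3p	0.01	0.19	0.19	15.21	4.25	6.34	up_both	Purple acid phosphatase-like protein
tae-miR1137	tae-miR1137	18.16	72.36	33.99	170.23	1.99	2.32	up_both	Pherophorin-C1 protein precursor
tae-miR1318-3p	osa-miR1318-3p	1.17	2.56	11.02	35.64	1.13	1.69	up_both
tae-miR1432	osa-miR1432	10.16	32.34	0.56	16.32	1.67	4.85	up_both	Mitochondrial phosphate transporter
tae-miR5368	gma-miR5368	1671.09	3890.36	580.25	2146.66	1.22	1.89	up_both
tae-miR159a	ath-miR159a	1036.32	4.08	19.40	1.28	-7.99	-3.92	down_both	MYB3
tae-miR159b	mdm-miR159b	0.17	0.01	2.45	0.17	-4.06	-3.84	down_both	MYB3
tae-miR159c-5p	aly-miR159c-5p	36.73	4.27	18.64	6.92	-3.11	-1.43	down_both	Dihydro-flavanoid reductase-like protein
tae-miR171f	sbi-miR171f	3.00	0.19	2.45	0.26	-3.98	-3.26	down_both	Sensor histidine kinase
tae-miR395i	osa-miR395i	0.75	0.19	7.25	1.88	-1.98	-1.95	down_both	ATP sulfurylase
tae-miR916	cre-miR916	18.49	7.97	21.19	7.95	-1.21	-1.41	down_both
tae-miR160a	vvi-miR160a	5.16	0.19	0.19	13.33	-4.77	6.15	opposite	ARF
tae-miR164b	sbi-miR164b	15.24	0.01	0.19	1.37	-10.57	2.86	opposite	NAC
tae-miR166h	cme-miR166h	5.83	0.85	0.38	0.94	-2.77	1.32	opposite	HD-ZIP4
tae-miR169d	vvi-miR169d	4.50	0.28	0.19	5.73	-3.98	4.93	opposite	CCAAT-box transcription factor
tae-miR172a	bdi-miR172a	7.66	2.75	0.28	2.31	-1.48	3.03	opposite	Succinyl CoA ligase beta subunit-like protein
tae-miR319c	ppt-miR319c	6.41	0.38	0.19	1.20	-4.08	2.67	opposite	Acyl-CoA synthetase
tae-miR393b	mdm-miR393b	8.08	1.04	1.22	410.19	-2.95	8.39	opposite	TIR1
tae-miR393i	gma-miR393i	9.58	1.99	0.19	26.49	-2.27	7.14	opposite	TIR1
tae-miR396a	bdi-miR396a	129.69	29.11	12.62	332.6	-2.16	4.72	opposite	GRF
tae-miR396c	zma-miR396c	8169.46	7.24	6.44	3.84	-6.92	2.78	opposite	GRF
tae-miR396g	osa-miR396g	13.99	3.13	0.47	16.83	-2.16	5.16	opposite	GRF
tae-miR444d.3	osa-miR444d.3	5.83	0.38	0.01	0.17	-3.94	4.09	opposite	IF3
tae-miR827-5p	zma-miR827-5p	28.57	0.01	0.19	0.85	-11.48	2.18	opposite	PHD finger-like protein
tae-miR156h	mdm-miR156h	0.42	0.47	0.56	89.56	0.19	7.31	single_genotype	SBP
tae-miR159a.2	osa-miR159a.2	5.00	2.75	0.47	1538.47	-0.86	11.67	single_genotype	Ent-kaurene synthase
tae-miR319a-3p	osa-miR319a-3p	8.33	6.16	7.91	3.85	-0.43	-1.04	single_genotype	Probable dihydrodipicolinate reductase 1
tae-miR398	tae-miR398	1.67	3.03	53.11	453.43	0.87	3.09	single_genotype	Superoxide dismutase [Cu-Zn]
tae-miR528b-3p	zma-miR528b-3p	0.33	0.19	0.38	187.23	-0.81	8.96	single_genotype	Receptor protein kinase-like
tae-miR538a	ppt-miR538a	52.22	5.78	8.57	6.15	-3.17	-0.48	single_genotype
tae-miR1128	ssp-miR1128	0.67	0.76	2.17	0.85	0.19	-1.34	single_genotype	18S ribosomal RNA gene
tae-miR1310	pta-miR1310	73.38	75.96	98.40	35.21	0.05	-1.48	single_genotype
tae-miR1862b	osa-miR1862b	1.58	0.85	4.71	0.85	-0.89	-2.46	single_genotype	Myosin heavy chain class VIII A2 protein
tae-miR2911	peu-miR2911	343.66	641.75	322.24	864.82	0.90	1.42	single_genotype	Chlorophyll a/b-binding protein WCAB precursor
tae-miR5048b	hvu-miR5048b	116.53	736.59	170.82	312.09	2.66	0.87	single_genotype	Protein kinase domain containing protein
tae-miR5059	bdi-miR5059	7.75	7.11	17.99	7.78	-0.12	-1.21	single_genotype
tae-miR5648-5p	ath-miR5648-5p	6.75	2.56	1.51	0.77	-1.40	-0.97	single_genotype	Aquaporin NIP1-2
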