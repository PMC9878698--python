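sl_no	gene_id	protein	expression_ratio	mutant_id	growth_ratio	significant	algorithms	previously_reported
1	AT4G14400	Accelerated cell death 6 (ACD6)	0.06	SALK_059132	1.73	1	LR	1
1	AT4G14400	Accelerated cell death 6 (ACD6)	0.06	SALK_116079	1.46	1	LR	1
2	AT5G02360	Domain C1 containing protein	0.09	SALK_004531	1.75	1	LR	0
2	AT5G02360	Domain C1 containing protein	0.09	SALK_004524	2.46	1	LR	0
3	AT2G18260	AtSYP112	0.14	SALK_037621	2.47	1	EMMAX,LR	0
3	AT2G18260	AtSYP112	0.14	CS26712	2.21	1	EMMAX,LR	0
3	AT2G18260	AtSYP112	0.14	CS868715	1.87	1	EMMAX,LR	0
4	AT1G61310	NB-ARC LRR	0.43	SALK_125189	2.66	1	EMMAX,LR	0
4	AT1G61310	NB-ARC LRR	0.43	SALK_029306	1.56	1	EMMAX,LR	0
5	AT2G19110	Heavy metal ATPase 4	0.5	SALK_042898	2.1	1	EMMAX	0
5	AT2G19110	Heavy metal ATPase 4	0.5	SALK_093482	3.65	1	EMMAX	0
6	AT5G41750	TIR-NB-LRR	0.53	SALK_066101	1.34	1	EMMAX,LR	0
6	AT5G41750	TIR-NB-LRR	0.53	SALK_085020	1.64	1	EMMAX,LR	0
7	AT5G23420	High-mobility group box 6	0.62	SALK_138632	2.12	1	LR	0
7	AT5G23420	High-mobility group box 6	0.62	SALK_044693	1.56	1	LR	0
8	AT5G52460	F-box leucine-rich repeat protein	0.71	SALK_013776	2.77	1	EMMAX	0
8	AT5G52460	F-box leucine-rich repeat protein	0.71	SALK_031583	0.39	1	EMMAX	0
9	AT3G61600	LRB2; POZ/BTB containing G-protein 1	0.76	SALK_100118	2.36	1	LR	0
9	AT3G61600	LRB2; POZ/BTB containing G-protein 1	0.76	SALK_128387	2.78	1	LR	0
10	AT3G24900	Receptor-like protein 39	1.31	CS868997	0.74	1	EMMAX	0
10	AT3G24900	Receptor-like protein 39	1.31	SALK_126504	0.6	1	EMMAX	0
11	AT1G31870	Bud site-selection protein 13	1.52	SALK_018219	1.77	1	EMMAX,LR	0
11	AT1G31870	Bud site-selection protein 13	1.52	SALK_096851	1.58	1	EMMAX,LR	0
12	AT2G19060	SGNH hydrolase-type esterase	1.68	SALK_061864	2.47	1	EMMAX,LR	0
12	AT2G19060	SGNH hydrolase-type esterase	1.68	SALK_117794	1.72	1	EMMAX,LR	0
12	AT2G19060	SGNH hydrolase-type esterase	1.68	SALK_115819	1.86	1	EMMAX,LR	0
13	AT2G04300	Leucine-rich repeat protein kinase	4.37	SALK_003316	2.3	1	EMMAX,LR	0
13	AT2G04300	Leucine-rich repeat protein kinase	4.37	SALK_003328	1.85	1	EMMAX,LR	0
14	AT4G12040	Stress-associated protein 7	5.97	SALK_071408	-1.03	1	LR	0
14	AT4G12040	Stress-associated protein 7	5.97	SALK_071504	0.58	1	LR	0
15	AT4G12000	SNARE associated Golgi protein	10.37	SALK_021373	0.51	1	EMMAX	0
15	AT4G12000	SNARE associated Golgi protein	10.37	SALK_204172	0.67	1	EMMAX	0
16	AT2G31360	16:0 delta 9 desaturase 2	26.04	SALK_079963	0.05	1	EMMAX	1
16	AT2G31360	16:0 delta 9 desaturase 2	26.04	SALK_016783	-0.49	1	EMMAX	1
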