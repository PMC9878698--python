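sl_no	gene_id	protein	expression_ratio	mutant_id	growth_ratio	significant	algorithms	previously_reported
1	AT3G61480	Quinoprotein amine dehydrogenase	0.84	SALK_017426	1.49	1	LR	0
1	AT3G61480	Quinoprotein amine dehydrogenase	0.84	SALK_099827	0.96	0	LR	0
2	AT1G31640	Agamous-like 92	0.85	SALK_030847C	1.79	1	EMMAX	0
2	AT1G31640	Agamous-like 92	0.85	SALK_035114C	1.17	0	EMMAX	0
3	AT2G27120	DNA polymerase epsilon catalytic subunit	0.92	SALK_025607	2.52	1	LR	0
3	AT2G27120	DNA polymerase epsilon catalytic subunit	0.92	SALK_056503	0.81	0	LR	0
4	AT3G53520	UDP-glucuronic acid decarboxylase 1	1.07	SALK_068865	1.36	1	EMMAX,LR	0
4	AT3G53520	UDP-glucuronic acid decarboxylase 1	1.07	SALK_152673	1.25	0	EMMAX,LR	0
5	AT2G39840	Type 1 phosphoprotein Ser/Thr phosphatase	1.34	SALK_090980	0.97	0	EMMAX,LR	0
5	AT2G39840	Type 1 phosphoprotein Ser/Thr phosphatase	1.34	SALK_090981	1.22	0	EMMAX,LR	0
5	AT2G39840	Type 1 phosphoprotein Ser/Thr phosphatase	1.34	CS375515	-0.73	1	EMMAX,LR	0
6	AT4G12350	AtMYB42	1.37	SALK_003422	1.28	1	EMMAX	0
6	AT4G12350	AtMYB42	1.37	SALK_032016	0.86	0	EMMAX	0
7	AT5G54960	Pyruvate decarboxylase-2	2.43	SALK_053107	0.48	1	EMMAX	0
8	AT3G43148	Myosin heavy chain-like protein	NA	SALK_151592	0.55	1	EMMAX	0
8	AT3G43148	Myosin heavy chain-like protein	NA	SALK_076725	0.96	0	EMMAX	0
9	AT5G39500	Endoplasmic reticulum morphology 1	NA	SALK_020371	0.57	1	EMMAX	0
9	AT5G39500	Endoplasmic reticulum morphology 1	NA	SALK_091078	1.21	0	EMMAX	0
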