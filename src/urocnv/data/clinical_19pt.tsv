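patient_id	cohort	treatment	age_dx	tnm	gleason	initial_treatment	months_dx_to_hspc	months_dx_to_crpc	months_adt_to_crpc	volume	psa_t1	psa_t2	interval_days	followup_months	event
1001	CRPC	Chemo	62	T4N1M1	9	ADT	0	7	7	High Volume	8.2	0.42	147	37.07	0
1002	CRPC	Chemo	66	T2cNxM1	NA	ADT	0	27	27	Low Volume	9.3	1.6	89	17.47	1
1003	CRPC	Chemo	54	T3aN0M0	7	Radical Prostatectomy	52	59	7	High Volume	107	162	84	6.77	1
1004	CRPC	Chemo	69	T3aNxM0	8	Radical Prostatectomy	18	60	42	Low Volume	3.4	4.6	92	59.07	0
1005	CRPC	Chemo	69	T3bN2M1	9	ADT	0	8	8	High Volume	0.48	0.1	146	9.53	1
1010	CRPC	Chemo	72	T3bN1M0	9	Radical Prostatectomy+ADT+Chemotherapy	0	50	50	High Volume	5	NA	144	21.83	1
1014	CRPC	Chemo	61	T2bN1M1	7	ADT	0	4	4	High Volume	126	56.8	99	20.1	1
1017	CRPC	Chemo	63	T2aN0M0	5	Radical Prostatectomy	12	206	194	Low Volume	22	104	139	56.7	0
1043	CRPC	Chemo	73	T2aNxM1	7	ADT	0	37	37	High Volume	15.5	8	80	33.1	0
1060	CRPC	Chemo	78	TxNxM1	NA	ADT	0	9	9	High Volume	3.7	1.4	104	18.93	1
1015	HSPC	ADT	67	T2cNxM0	7	Radical Prostatectomy	30	NR	NR	Low Volume	1	0.9	98	54.23	0
1028	HSPC	ADT	49	T3bN0M0	9	Radical Prostatectomy+ADT	0	96	96	Low Volume	0.33	0.12	154	47.67	0
1040	HSPC	ADT	53	T2NxM0	9	Laparoscopic Prostatectomy	10	NR	NR	Low Volume	2.5	<0.10	168	40.93	0
1050	HSPC	ADT	64	T3bN1M1	9	Radiation+ADT	0	48	48	Low Volume	4.2	<0.10	136	55.13	0
1059	HSPC	ADT	62	T3bN1M0	9	Radical Prostatectomy+ADT	0	NR	NR	Low Volume	2.9	<0.10	116	54.23	0
1080	HSPC	ADT	65	T3bN1M0	8	Radiation+ADT	0	NR	NR	Low Volume	16	0.77	172	54.86	0
1084	HSPC	ADT	57	T3bN0M0	9	Radical Prostatectomy	2	8	6	High Volume	2.2	0.24	78	53.07	0
1098	HSPC	ADT	78	T2aNxM0	6	External Beam Radiation Therapy	60	NR	NR	Low Volume	5.7	0.54	131	51.57	0
1104	HSPC	ADT	67	T2cN1M1	8	ADT+Chemotherapy	0	12	12	Low Volume	37	<0.10	99	52	0
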