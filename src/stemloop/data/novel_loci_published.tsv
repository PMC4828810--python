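miRNA-name	Sequence	Length	GC%	TPM female	TPM male	Folding energy	MFEI	Unigene	Start	End	Strand
aof-miRn01	AAAUUCCAGACGGUCGGCGGGC	22	63.2	11.43	11.92	-193.90	1.53	UN09382	28	210	+
aof-miRn01	AAAUUCCAGACGGUCGGCGGGC	22	63.2	11.43	11.92	-212.60	1.44	UN07381	24	233	+
aof-miRn02	AAAUUCCAGACGGUCGGCGGGCU	23	60.9	10.29	12.24	-213.30	1.44	UN07381	23	234	+
aof-miRn03	AAUAGAUGAGAUGAGAUGAGUUGU	24	33.4	5.03	7.06	-87.94	2.00	UN00358	39	209	+
aof-miRn04	AAUUCCAGACGGUCGGCGGGC	21	66.7	10.29	14.12	-212.60	1.44	UN07381	24	233	+
aof-miRn04	AAUUCCAGACGGUCGGCGGGC	21	66.7	10.29	14.12	-193.90	1.53	UN09382	28	210	+
aof-miRn05	AAUUCCAGACGGUCGGCGGGCU	22	63.6	11.89	13.49	-213.30	1.44	UN07381	23	234	+
aof-miRn06	AGACGGUCGGCGGGCUGAAU	20	65.0	20.12	28.39	-215.50	1.44	UN07381	19	238	+
aof-miRn07	AGACGGUCGGCGGGCUGAAUC	21	66.7	24.46	33.10	-215.50	1.43	UN07381	19	239	+
aof-miRn08	AGCGGGGUGUUCUGAUCCAUA	21	52.4	5.03	1.88	-33.40	0.90	UN45561	155	243	+
aof-miRn09	AGCGGGGUGUUCUGAUCCAUACAA	24	50.0	9.83	3.29	-33.40	0.90	UN45561	155	243	+
aof-miRn10	AUGCGAGCGGGGUGUUCUGAUCCA	24	58.3	18.98	13.49	-42.70	1.02	UN45561	150	248	+
aof-miRn11	AUUCCAGACGGUCGGCGGGC	20	70.0	13.95	10.67	-193.90	1.53	UN09382	28	210	+
aof-miRn11	AUUCCAGACGGUCGGCGGGC	20	70.0	13.95	10.67	-212.60	1.44	UN07381	24	233	+
aof-miRn12	AUUCCAGACGGUCGGCGGGCU	21	66.7	14.86	9.73	-213.30	1.44	UN07381	23	234	+
aof-miRn13	CAGACGGUCGGCGGGCUGAA	20	70.0	9.15	12.39	-215.20	1.43	UN07381	19	237	+
aof-miRn14	CAGACGGUCGGCGGGCUGAAU	21	66.7	23.32	31.69	-215.50	1.44	UN07381	19	238	+
aof-miRn15	CAGACGGUCGGCGGGCUGAAUC	22	68.2	25.15	40.94	-215.70	1.42	UN07381	18	239	+
aof-miRn16	CCAGACGGUCGGCGGGCUGA	20	75.0	13.49	16.00	-215.20	1.43	UN07381	20	236	+
aof-miRn17	CCAGACGGUCGGCGGGCUGAA	21	71.4	4.57	9.10	-215.20	1.43	UN07381	19	237	+
aof-miRn18	CCAGACGGUCGGCGGGCUGAAU	22	68.2	18.29	17.88	-215.70	1.44	UN07381	18	238	+
aof-miRn19	CCAGACGGUCGGCGGGCUGAAUC	23	69.6	22.64	33.26	-215.70	1.43	UN07381	18	239	+
aof-miRn20	CCUGGUUCCCUGUAUGCCACC	21	61.9	27.44	18.51	-45.50	0.99	UN21911	249	331	+
aof-miRn21	CGAAAUUCCAGACGGUCGGCGGGC	24	66.7	8.69	8.16	-193.90	1.53	UN09382	28	210	+
aof-miRn21	CGAAAUUCCAGACGGUCGGCGGGC	24	66.7	8.69	8.16	-212.60	1.44	UN07381	24	233	+
aof-miRn22	CGAACCCUGGUCGAUUGUUUU	21	47.6	10.29	12.71	-52.44	0.65	UN41527	26	234	+
aof-miRn23	CGAACCCUGGUCGAUUGUUUUU	22	45.5	2.52	6.43	-53.04	0.65	UN41527	25	235	+
aof-miRn24	CGAUUGUUUUUGGGAUGCGCU	21	47.6	4.34	5.65	-32.70	0.62	UN21248	7	116	+
aof-miRn25	CUGGUUCCCUGUAUGCCACCC	21	61.9	25.38	17.26	-45.50	1.03	UN21911	250	330	+
aof-miRn25*	GCGUGCAUGGAACCAAGCAUG	21	52.2	5.11	2.56	-93.80	1.00	UN21911	250	330	+
aof-miRn26	GAAAUUCCAGACGGUCGGCGGGC	23	65.2	7.77	6.27	-193.90	1.53	UN09382	28	210	+
aof-miRn26	GAAAUUCCAGACGGUCGGCGGGC	23	65.2	7.77	6.27	-212.60	1.44	UN07381	24	233	+
aof-miRn27	GAAAUUCCAGACGGUCGGCGGGCU	24	62.5	6.63	5.80	-213.30	1.44	UN07381	23	234	+
aof-miRn28	GUGCCUGGUUCCCUGUAUGCC	21	61.9	730.06	744.81	-50.40	1.03	UN21911	246	334	+
aof-miRn29	GUGCUUCCCCUCGUUGUCACC	21	61.9	0.00	10.04	-43.60	0.78	UN05913	103	192	+
aof-miRn30	UAAAUAGUCGGGGUUGCCAACC	22	50.0	3.89	9.57	-43.20	1.20	UN31232	131	39	-
aof-miRn31	UAAAUAGUCGGGGUUGGCAACC	22	50.0	5.94	6.27	-43.20	1.14	UN42854	153	60	-
aof-miRn31	UAAAUAGUCGGGGUUGGCAACC	22	50.0	5.94	6.27	-68.90	1.50	UN31232	27	143	+
aof-miRn32	UGAUUAUGUAGUGGUCCCUCC	21	47.6	7.77	9.88	-63.94	0.98	UN22735	161	338	+
aof-miRn33	UGGCGUGCAUGGAAUCAAGCA	21	52.4	13.72	5.80	-49.10	1.02	UN21911	247	333	+
aof-miRn34	UGGUCGAUUGUUUUUGGGAUG	21	42.9	26.75	21.49	-30.90	0.63	UN21248	10	112	+
aof-miRn35	UGGUCGAUUGUUUUUGGGAUGC	22	45.5	4.57	6.12	-31.40	0.63	UN21248	9	113	+
aof-miRn36	UGUGAUUAUGUAGUGGUCCCUCC	23	47.8	8.46	6.12	-63.94	0.98	UN22735	161	338	+
aof-miRn37	UGUGAUUAUGUAGUGGUCCCUCCA	24	45.8	5.72	5.96	-65.64	1.01	UN22735	160	339	+
aof-miRn38	UUGCCUACUCCGCCCAUUCCCC	22	63.6	251.74	222.75	-45.10	1.13	UN22494	52	141	+
aof-miRn39	UUUCCAAUGCCUCCCAUUCCGG	22	54.5	109.06	102.91	-23.70	0.91	UN16232	530	464	-
aof-miRn39	UUUCCAAUGCCUCCCAUUCCGG	22	54.5	109.06	102.91	-27.00	0.96	UN17918	30	96	+
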