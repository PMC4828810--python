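miRNA-name	Sequence	Length	Family	TPM female	TPM male	Female/male	Log2 (fold change)
aof-miR1425-5p	UAGGAUUCAAUCCUUGCUGCU	21	miR1425	1.37	6.27	0.219	-2.1910
aof-miR156k	UGACAGAAGAGAGAGAGCAC	20	miR156	59.22	2.51	23.594	4.5603
aof-miR156a	UUGACAGAAGAGAGUGAGCAC	21	miR156	0.23	7.69	0.030	-5.0589
aof-miR159b	UUUGGAUUGAAGGGAGCUCUG	21	miR159	4.80	52.86	0.091	-3.4580
aof-miR160c	GCGUGCGAGGAGCCAAGCAUA	21	miR160	5.72	0.78	7.333	2.8744
aof-miR160b	UGCCUGGUUCCCUGUAUGCC	20	miR160	11.89	5.96	1.943	0.9583
aof-miR160d	UGCCUGGUUCCCUGUAUGCCA	21	miR160	114.55	51.14	2.240	1.1635
aof-miR160a	UGCCUGGCUCCCUGUAUGCCA	21	miR160	21.95	8.47	2.591	1.3735
aof-miR164c	GGAGAAGCAGGGCACGUGCA	20	miR164	13.72	6.75	2.033	1.0236
aof-miR164a	UGGAGAAGCAGGACACGUGC	20	miR164	5.03	2.35	2.140	1.0976
aof-miR164e	UGGAGAAGCAGGACACGUGCA	21	miR164	48.70	11.29	4.314	2.1090
aof-miR166a-2	GGAAUGUUGUCUGGCUCGUG	20	miR166	6.40	1.25	5.120	2.3561
aof-miR166b-1	GGAAUGUUGUCUGGCUCGUGG	21	miR166	83.00	35.14	2.362	1.2400
aof-miR166e-2	UCCGACCAGGCUUCAUUCCCC	21	miR166	5.72	0.63	9.079	3.1825
aof-miR166e-4	UCGCACCAGGCUUCAUUCCCC	21	miR166	5.49	1.88	2.920	1.5460
aof-miR166e-6	UCGGACCACGCUUCAUUCCCC	21	miR166	6.86	2.98	2.302	1.2029
aof-miR166e-7	UCGGACCAGACUUCAUUCCCC	21	miR166	10.75	28.55	0.377	-1.4074
aof-miR166e-8	UCGGACCAGCCUUCAUUCCCC	21	miR166	8.00	21.80	0.367	-1.4461
aof-miR166e-9	UCGGACCAGCCUUCAUUCCUC	21	miR166	0.91	5.02	0.181	-2.4659
aof-miR166e-10	UCGGACCAGGCCUCAUUCCCC	21	miR166	12.58	5.33	2.360	1.2388
aof-miR166e-11	UCGGACCAGGCUCCAUUCCCC	21	miR166	8.46	1.73	4.890	2.2898
aof-miR165a	UCGGACCAGGCUUCAUCCCCC	21	miR166	661.69	1436.29	0.461	-1.1172
aof-miR166l-2	UCGGACCAGGCUUCAUUUCUC	21	miR166	2.52	6.12	0.412	-1.2793
aof-miR166i-6	UCGGACCAGUCUUCAUUCCCC	21	miR166	1.60	13.33	0.120	-3.0589
aof-miR166k-1	CUCGGACCAGGCUUCAUCCCC	21	miR166	1.37	15.37	0.089	-3.4901
aof-miR166d-2	UCGGACCAGGCUUCAUUACCC	21	miR166	5.03	1.25	4.024	2.0086
aof-miR166d-4	UCGGCCCAGGCUUCAUUCCCC	21	miR166	17.61	1.57	11.217	3.4876
aof-miR166d-5	UCGGGCCAGGCUUCAUUCCCC	21	miR166	46.19	5.02	9.201	3.2018
aof-miR166d-6	UCGGGCCAGGCUUCAUUCCUC	21	miR166	6.63	1.10	6.027	2.5914
aof-miR166i-9	UCGGUCCAGGCUUCAUUCCCC	21	miR166	8.69	0.94	9.245	3.2087
aof-miR166b-p3	UCUCAGACCAGGCUUCAUUCC	21	miR166	6.63	2.67	2.483	1.3121
aof-miR166a-5	UCUCGGACCCGGCUUCAUUCC	21	miR166	0.46	7.37	0.062	-4.0116
aof-miR166m-1	UCGGACCAGGCUUCAUUCCUUU	22	miR166	2.29	6.27	0.365	-1.4540
aof-miR167g	UGAAGCUGCCAGCAUGAUC	19	miR167	117.74	54.25	2.170	1.1177
aof-miR167b	GGUCAUGCUCUGACAGCCUCACU	23	miR167	10.52	3.29	3.198	1.6772
aof-miR168d	CGCUUGGUGCAGGUCGGGAA	20	miR168	5.26	2.04	2.578	1.3663
aof-miR168f	CCCGCCUUGCACCAAGUGAAU	21	miR168	1.14	11.61	0.098	-3.3511
aof-miR168e	UCGCUUGGUGCAGGUCGGGU	20	miR168	13.03	1.88	6.931	2.7931
aof-miR168a-2	UCGCUUGGUGCAGAUCGGGAC	21	miR168	6.63	57.41	0.115	-3.1203
aof-miR168a-4	GAUCCCGCCUUGCACCAAGUGAAU	24	miR168	0.69	7.53	0.092	-3.4422
aof-miR171f	UGAUUGAGCCGUGCCAAUAUC	21	miR171	128.27	39.06	3.284	1.7155
aof-miR172b	GUGGCACCAUCAAGAUUCACA	21	miR172	27.67	8.00	3.459	1.7904
aof-miR390c	AGCUCAGGAGGGAUAGCGCC	20	miR390	5.94	1.57	3.783	1.9195
aof-miR390a	AAGCUCAGGAGGGAUAGCGCC	21	miR390	332.68	94.91	3.505	1.8094
aof-miR393a	UCCAAAGGGAUCGCAUUGAUC	21	miR393	5.49	2.35	2.336	1.2240
aof-miR393b	UCCAAAGGGAUCGCAUUGAUCU	22	miR393	37.95	9.10	4.170	2.0600
aof-miR396a-5p	UUCCACAGCUUUCUUGAACU	20	miR396	24.24	60.55	0.400	-1.3219
aof-miR396f	UCCACAGGCUUUCUUGAACUG	21	miR396	3.66	18.20	0.201	-2.3147
aof-miR396g	UUCCACAGCCUUCUUGAACUG	21	miR396	1.83	6.12	0.299	-1.7418
aof-miR396b-4	UUCCACAGCUUUCUUGAACUU	21	miR396	3.89	10.82	0.360	-1.4739
aof-miR408a	UGCACUGCCUCUUCCCUGGC	20	miR408	7.09	23.69	0.299	-1.7418
aof-miR408b	UGCACUGCCUCUUCCCUGGCU	21	miR408	32.24	170.99	0.189	-2.4035
cme-miR408c	UGCACUGCCUCUUCCCUGGCUU	22	miR408	13.49	59.61	0.226	-2.1456
aof-miR171h	UGAGCCGAACCAAUAUCACUC	21	miR479	185.20	46.59	3.975	1.9910
aof-miR5179	UUUUGCUCAAGACCGCGCAAC	21	miR5179	97.17	47.37	2.051	1.0363
aof-miR827c	UUAGAUGACCAUCAACAAACA	21	miR827	377.95	167.85	2.252	1.1712
aof-miRn08	AGCGGGGUGUUCUGAUCCAUA	21		5.03	1.88	2.676	1.4201
aof-miRn09	AGCGGGGUGUUCUGAUCCAUACAA	24		9.83	3.29	2.988	1.5792
aof-miRn17	CCAGACGGUCGGCGGGCUGAA	21		4.57	9.10	0.502	-0.9942
aof-miRn23	CGAACCCUGGUCGAUUGUUUUU	22		2.52	6.43	0.392	-1.3511
aof-miRn29	GUGCUUCCCCUCGUUGUCACC	21		0.00	10.04	0.000
aof-miRn30	UAAAUAGUCGGGGUUGCCAACC	22		3.89	9.57	0.406	-1.3004
aof-miRn33	UGGCGUGCAUGGAAUCAAGCA	21		13.72	5.80	2.366	1.2425
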