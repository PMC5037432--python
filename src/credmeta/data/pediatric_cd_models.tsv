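gene	variant_id	phenotype	n_cases	n_controls	model	n_studies	or_	ci_low	ci_high	p	i2	power	bfdp	venice	egger_detected	carrier_only
NOD2	rs2066844	CD	1984	4179	dominant	16	2.23	1.88	2.64	4.77e-20	46	1.00	0.000	ABB	False	False
NOD2	rs2066844	CD	1984	4179	recessive	12	4.14	2.18	7.89	1.54e-05	0	0.99	0.035	AAB	False	False
NOD2	rs2066844	CD	1984	4179	additive1	16	2.11	1.77	2.52	9.81e-17	36	1.00	0.000	ABB	False	False
NOD2	rs2066844	CD	1984	4179	additive2	12	4.44	2.34	8.43	5.26e-06	0	0.99	0.016	AAB	False	False
NOD2	rs2066845	CD	2059	4274	dominant	16	3.21	2.25	4.60	1.61e-10	53	1.00	0.000	ACB	False	False
NOD2	rs2066845	CD	2059	4274	recessive	11	8.64	2.80	26.69	1.77e-04	0	1.00	0.465	AAB	False	False
NOD2	rs2066845	CD	2059	4274	additive1	16	3.02	2.42	3.76	5.04e-23	50	1.00	0.000	ABB	False	False
NOD2	rs2066845	CD	2059	4274	additive2	11	9.18	2.99	28.22	1.09e-04	0	1.00	0.405	AAB	False	False
NOD2	rs2066847	CD	1980	4234	dominant	16	5.78	3.67	9.11	4.12e-14	77	1.00	0.000	ACB	False	False
NOD2	rs2066847	CD	1980	4234	recessive	10	91.00	25.07	330.27	6.97e-12	0	1.00	0.000	AAB	False	False
NOD2	rs2066847	CD	1980	4234	additive1	16	5.03	3.34	7.59	1.34e-14	70	1.00	0.000	ACB	False	False
NOD2	rs2066847	CD	1980	4234	additive2	10	105.94	30.65	366.14	1.72e-13	0	1.00	0.000	AAB	False	False
NOD2	rs5743289	CD	376	687	dominant	3	1.48	1.13	1.94	0.004	0	0.83	0.640	AAB	False	True
IL23R	rs11209026	CD	1158	4766	dominant	10	0.32	0.23	0.43	2.10e-13	0	1.00	0.000	AAB	False	False
IL23R	rs11209026	CD	1158	4766	recessive	7	0.97	0.31	3.04	0.952	0	0.05	0.963	CAB	False	False
IL23R	rs11209026	CD	1158	4766	additive1	10	0.33	0.24	0.44	8.29e-13	0	1.00	0.000	AAB	False	False
IL23R	rs11209026	CD	1158	4766	additive2	7	0.88	0.29	2.76	0.823	0	0.06	0.963	CAB	False	False
IL23R	rs7517847	CD	496	1383	dominant	4	0.66	0.53	0.83	3.13e-04	0	0.95	0.180	AAB	False	False
IL23R	rs7517847	CD	496	1383	recessive	4	0.57	0.41	0.79	8.97e-04	49	0.96	0.262	ABB	False	False
IL23R	rs7517847	CD	496	1383	additive1	4	0.73	0.58	0.93	0.010	0	0.80	0.800	AAB	False	False
IL23R	rs7517847	CD	496	1383	additive2	4	0.47	0.32	0.67	4.11e-05	45	1.00	0.023	ABB	False	False
IBD5	rs11739135	CD	536	722	dominant	4	1.24	0.97	1.59	0.082	48	0.41	0.956	CBB	False	False
IBD5	rs11739135	CD	536	722	recessive	4	1.41	1.05	1.89	0.024	28	0.63	0.862	BBB	False	False
IBD5	rs11739135	CD	536	722	additive1	4	1.17	0.90	1.51	0.245	15	0.23	0.977	CAB	False	False
IBD5	rs11739135	CD	536	722	additive2	4	1.55	1.11	2.17	0.011	56	0.73	0.767	BCB	False	False
IBD5	rs12521868	CD	536	731	dominant	4	1.35	1.05	1.73	0.018	0	0.68	0.856	BAB	False	False
IBD5	rs12521868	CD	536	731	recessive	4	1.76	1.31	2.35	1.55e-04	0	0.97	0.072	AAB	False	False
IBD5	rs12521868	CD	536	731	additive1	4	1.20	0.92	1.55	0.178	0	0.28	0.971	CAB	False	False
IBD5	rs12521868	CD	536	731	additive2	4	1.88	1.34	2.62	2.22e-04	0	0.96	0.101	AAB	False	False
IBD5	rs17622208	CD	527	872	dominant	3	1.38	1.05	1.81	0.020	51	0.83	0.861	ACB	False	False
IBD5	rs17622208	CD	527	872	recessive	2	1.28	0.92	1.78	0.140	0	0.33	0.961	CAB	False	False
IBD5	rs17622208	CD	527	872	additive1	3	1.33	1.00	1.78	0.050	53	0.54	0.930	BCB	False	False
IBD5	rs17622208	CD	527	872	additive2	2	1.61	1.09	2.37	0.020	34	0.64	0.811	BBB	False	False
IBD5	rs1050152	CD	757	1534	dominant	7	1.20	0.98	1.47	0.072	0	0.45	0.959	CAB	False	False
IBD5	rs1050152	CD	757	1534	recessive	7	1.48	1.17	1.86	9.91e-04	0	0.93	0.293	AAB	False	False
IBD5	rs1050152	CD	757	1534	additive1	7	1.09	0.88	1.35	0.416	0	0.13	0.987	CAB	False	False
IBD5	rs1050152	CD	757	1534	additive2	7	1.55	1.18	2.02	0.001	0	0.92	0.360	AAB	False	False
IBD5	rs26313667	CD	653	1117	dominant	5	1.40	1.11	1.77	0.005	0	0.82	0.675	AAB	False	False
IBD5	rs26313667	CD	653	1117	recessive	5	1.42	1.13	1.78	0.003	0	0.87	0.527	AAB	False	False
IBD5	rs26313667	CD	653	1117	additive1	5	1.28	1.00	1.64	0.051	0	0.51	0.934	BAB	False	False
IBD5	rs26313667	CD	653	1117	additive2	5	1.68	1.26	2.23	3.67e-04	0	0.96	0.153	AAB	False	False
ATG16L1	rs2241880	CD	1360	6385	dominant	12	0.70	0.62	0.81	3.14e-07	0	1.00	0.002	AAB	False	False
ATG16L1	rs2241880	CD	1360	6385	recessive	12	0.73	0.62	0.87	2.70e-04	0	0.90	0.225	ACB	False	False
ATG16L1	rs2241880	CD	1360	6385	additive1	12	0.74	0.64	0.86	4.14e-05	0	0.98	0.067	AAB	False	False
ATG16L1	rs2241880	CD	1360	6385	additive2	12	0.61	0.51	0.74	2.85e-07	4	1.00	0.001	AAB	False	False
DLG5	rs1248696	CD	427	846	dominant	4	0.79	0.57	1.09	0.148	0	0.34	0.961	CAB	False	False
DLG5	rs1248696	CD	427	846	recessive	4	0.56	0.14	2.26	0.416	0	0.12	0.955	CAB	False	False
DLG5	rs1248696	CD	427	846	additive1	4	0.80	0.57	1.12	0.192	0	0.27	0.968	CAB	False	False
DLG5	rs1248696	CD	427	846	additive2	4	0.55	0.14	2.21	0.397	0	0.13	0.955	CAB	False	False
DLG5	rs2289311	CD	165	750	dominant	3	0.76	0.53	1.10	0.151	19	0.36	0.958	CAB	False	False
DLG5	rs2289311	CD	165	750	recessive	3	0.55	0.29	1.06	0.075	0	0.50	0.920	BAB	False	False
DLG5	rs2289311	CD	165	750	additive1	3	0.84	0.57	1.23	0.371	4	0.16	0.976	CAB	False	False
DLG5	rs2289311	CD	165	750	additive2	3	0.51	0.26	1.01	0.053	0	0.58	0.954	BAB	False	False
PSMG1	rs2836878	CD	425	705	dominant	3	1.06	0.83	1.36	0.623	43	0.07	0.987	CBB	False	False
PSMG1	rs2836878	CD	425	705	recessive	3	0.98	0.33	2.91	0.971	67	0.05	0.964	CCB	False	False
PSMG1	rs2836878	CD	425	705	additive1	3	1.13	0.88	1.46	0.339	0	0.16	0.982	CAB	False	False
PSMG1	rs2836878	CD	425	705	additive2	3	1.10	0.33	3.72	0.872	72	0.07	0.962	CCB	False	False
TNF-a	rs1800629	CD	509	1443	dominant	5	1.98	1.29	3.03	0.002	57	1.00	0.415	ACB	False	False
TNF-a	rs1800629	CD	509	1443	recessive	4	3.79	1.96	7.32	7.52e-05	0	0.98	0.101	AAB	False	False
TNF-a	rs1800629	CD	509	1443	additive1	5	1.91	1.27	2.85	0.002	51	1.00	0.397	ACB	False	False
TNF-a	rs1800629	CD	509	1443	additive2	4	4.75	2.43	9.26	4.86e-06	0	1.00	0.017	AAB	False	False
TNF-a	rs1799724	CD	326	854	dominant	3	0.90	0.67	1.22	0.501	47	0.10	0.983	CBB	False	False
TNF-a	rs1799724	CD	326	854	recessive	3	0.63	0.28	1.41	0.259	0	0.13	0.955	CAB	False	False
TNF-a	rs1799724	CD	326	854	additive1	3	0.94	0.69	1.29	0.718	47	0.07	0.985	CBB	False	False
TNF-a	rs1799724	CD	326	854	additive2	3	0.60	0.26	1.36	0.221	0	0.15	0.952	CAB	False	False
PTPN2	rs2542151	CD	461	2152	dominant	3	1.05	0.83	1.33	0.667	0	0.07	0.988	CAB	False	False
PTPN2	rs2542151	CD	461	2152	recessive	3	1.77	0.88	3.55	0.108	0	0.42	0.934	CAB	False	False
PTPN2	rs2542151	CD	461	2152	additive1	3	1.01	0.79	1.28	0.955	0	0.05	0.989	CAB	False	False
PTPN2	rs2542151	CD	461	2152	additive2	3	1.77	0.88	3.56	0.108	0	0.42	0.934	CAB	False	False
TLR4	rs4986790	CD	214	369	dominant	3	1.54	0.92	2.58	0.100	20	0.38	0.937	CAB	False	True
BSN-MST1	rs9858542	CD	414	679	dominant	3	2.08	1.62	2.68	1.00e-05	13	1.00	0.030	AAB	False	True
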