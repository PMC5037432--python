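gene	variant_id	phenotype	n_cases	n_controls	model	n_studies	or_	ci_low	ci_high	p	i2	power	bfdp	venice	egger_detected	carrier_only
NOD2	rs2066844	UC	590	1512	dominant	6	1.66	1.20	2.28	0.002	34	0.88	0.427	ABB	False	False
NOD2	rs2066844	UC	590	1512	recessive	4	0.96	0.20	4.68	0.960	0	0.05	0.959	CAB	False	False
NOD2	rs2066844	UC	590	1512	additive1	6	1.73	1.25	2.36	8.80e-04	34	0.88	0.215	ABB	False	False
NOD2	rs2066844	UC	590	1512	additive2	4	1.02	0.21	5.00	0.980	0	0.05	0.959	CAB	False	False
NOD2	rs2066845	UC	591	1515	dominant	6	1.14	0.70	1.87	0.600	0	0.09	0.976	CAB	False	False
NOD2	rs2066845	UC	591	1515	recessive	2	3.24	0.17	63.38	0.439	0	0.30	0.951	CAB	False	False
NOD2	rs2066845	UC	591	1515	additive1	6	1.11	0.68	1.84	0.600	0	0.09	0.976	CAB	False	False
NOD2	rs2066845	UC	591	1515	additive2	2	3.06	0.16	57.43	0.455	0	0.28	0.951	CAB	False	False
NOD2	rs2066847	UC	593	1502	dominant	6	1.76	1.11	2.80	0.010	0	0.74	0.813	BAB	False	False
NOD2	rs2066847	UC	593	1502	additive1	6	1.79	1.13	2.84	0.010	0	0.74	0.785	BAB	False	False
IL23R	rs11209026	UC	393	1321	dominant	3	0.55	0.37	0.84	0.005	0	0.85	0.653	AAB	False	False
IL23R	rs11209026	UC	393	1321	additive1	3	0.56	0.37	0.85	0.007	0	0.84	0.677	AAB	False	False
IBD5	rs1050152	UC	353	1056	dominant	4	1.22	0.93	1.61	0.150	0	0.31	0.968	CAB	False	False
IBD5	rs1050152	UC	353	1056	recessive	4	1.40	1.03	1.91	0.030	0	0.61	0.897	BAB	False	False
IBD5	rs1050152	UC	353	1056	additive1	4	1.12	0.84	1.50	0.430	0	0.12	0.983	CAB	False	False
IBD5	rs1050152	UC	353	1056	additive2	4	1.52	1.06	2.17	0.022	0	0.66	0.848	BAB	False	False
IBD5	rs26313667	UC	353	1044	dominant	4	1.30	0.97	1.75	0.081	0	0.46	0.947	CAB	False	False
IBD5	rs26313667	UC	353	1044	recessive	4	1.29	0.97	1.71	0.085	17	0.44	0.946	CAB	False	False
IBD5	rs26313667	UC	353	1044	additive1	4	1.22	0.89	1.67	0.209	0	0.25	0.971	CAB	False	False
IBD5	rs26313667	UC	353	1044	additive2	4	1.49	1.04	2.13	0.031	0	0.61	0.876	BAB	False	False
DLG5	rs1248696	UC	289	800	dominant	3	0.85	0.58	1.24	0.405	0	0.14	0.970	CAB	False	False
DLG5	rs1248696	UC	289	800	recessive	3	0.74	0.16	3.33	0.690	0	0.06	0.958	CAB	False	False
DLG5	rs1248696	UC	289	800	additive1	3	0.86	0.58	1.27	0.450	0	0.14	0.978	CAB	False	False
DLG5	rs1248696	UC	289	800	additive2	3	0.72	0.16	3.24	0.664	0	0.06	0.958	CAB	False	False
TNF-a	rs1800629	UC	235	844	dominant	3	1.81	0.82	3.99	0.143	69	0.95	0.941	ACB	False	False
TNF-a	rs1800629	UC	235	844	recessive	3	3.08	0.99	9.55	0.052	0	0.74	0.913	BAB	False	False
TNF-a	rs1800629	UC	235	844	additive1	3	1.65	1.10	2.47	0.015	61	0.83	0.802	ACB	False	False
TNF-a	rs1800629	UC	235	844	additive2	3	3.34	1.09	10.22	0.035	0	0.80	0.889	AAB	False	False
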