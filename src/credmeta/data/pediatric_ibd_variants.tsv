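gene	variant_id	phenotype	n_cases	n_controls	n_studies	ref_allele	raf_cases	raf_controls	maf	carrier_only
NOD2	rs2066844	CD	1984	4179	16	C	0.912	0.958	0.014	False
NOD2	rs2066845	CD	2059	4280	16	G	0.941	0.976	0.005	False
NOD2	rs2066847	CD	1980	4234	16	G	0.872	0.976	0.006	False
NOD2	rs5743289	CD	376	507	3	C			0.052	True
IL23R	rs11209026	CD	1158	4766	10	G	0.977	0.923	0.023	False
IL23R	rs7517847	CD	496	1383	4	T	0.654	0.588	0.356	False
IBD5	rs11739135	CD	536	722	4	G	0.548	0.592	0.135	False
IBD5	rs12521868	CD	536	742	4	G	0.525	0.596	0.138	False
IBD5	rs17622208	CD	527	872	3	G	0.673	0.681	0.190	False
IBD5	rs1050152	CD	757	1474	7	C	0.528	0.577	0.134	False
IBD5	rs26313667	CD	653	1117	5	G	0.462	0.523	0.267	False
ATG16L1	rs2241880	CD	1360	6385	12	G	0.594	0.543	0.396	False
DLG5	rs1248696	CD	427	846	4	C	0.919	0.898	0.034	False
DLG5	rs2289311	CD	165	750	3	G	0.700	0.646	0.262	False
PSMG1	rs2836878	CD	425	705	3	G	0.746	0.748	0.209	False
TNF-a	rs1800629	CD	509	1443	6	G	0.830	0.882	0.090	False
TNF-a	rs1799724	CD	326	854	3	C	0.842	0.870	0.099	False
PTPN2	rs2542151	CD	461	2152	4	T	0.858	0.862	0.174	False
TLR4	rs4986790	CD	214	369	3	A			0.060	True
BSN-MST1	rs9858542	CD	414	679	3	G			0.195	True
NOD2	rs2066844	UC	606	1512	6	C	0.94	0.96	0.014	False
NOD2	rs2066845	UC	591	1515	6	G	0.98	0.98	0.005	False
NOD2	rs2066847	UC	576	1240	6	G	0.97	0.98	0.006	False
IL23R	rs11209026	UC	358	1344	3	G	0.96	0.94	0.023	False
IBD5	rs1050152	UC	392	1056	4	C	0.53	0.57	0.134	False
IBD5	rs26313667	UC	392	1044	4	G	0.48	0.52	0.267	False
DLG5	rs1248696	UC	318	800	3	C	0.92	0.90	0.034	False
TNF-a	rs1800629	UC	235	844	3	G	0.87	0.88	0.090	False
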