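chrom	gene	p_ms	nsnps_ms	top_snp_ms	top_snp_p_ms	p_is	nsnps_is	top_snp_is	top_snp_p_is
2	LBH	8.34E-04	8	rs17321999	1.41E-04	1.39E-03	105	rs79251390	2.45E-04
2	STAT4	1.00E-04	20	rs6752770	2.48E-04	4.17E-02	239	rs35672585	1.25E-03
3	FOXP1	3.53E-04	137	rs1499895	4.51E-05	3.80E-02	700	rs7616330	9.97E-05
4	TEC	4.85E-04	37	rs17471024	6.21E-05	1.11E-02	494	rs73817607	2.69E-04
6	MICB	1.00E-06	4	rs2844498	1.58E-54	4.27E-03	213	rs2844498	7.51E-04
6	NFKBIL1	1.00E-06	3	rs6929796	1.05E-32	2.39E-02	68	rs114205738	6.99E-04
7	IL6	3.60E-05	2	rs2066992	1.89E-05	3.58E-02	20	rs2069832	1.32E-02
10	CAMK2G	4.52E-04	5	rs2675671	9.40E-04	2.44E-02	92	rs4746152	5.25E-03
12	B4GALNT1	7.10E-05	2	rs10083154	3.45E-06	3.98E-02	27	rs715930	1.94E-02
12	BRAP	1.93E-02	5	rs11065987	3.83E-03	3.96E-04	45	rs11065987	5.05E-05
12	CLEC2D	1.87E-04	6	rs3764021	1.24E-05	6.40E-03	105	rs7968401	1.53E-04
12	CLECL1	3.16E-04	5	rs10466829	1.09E-05	3.26E-04	106	rs2401391	1.55E-04
12	HECTD4	3.22E-02	11	rs11066188	2.14E-03	3.16E-04	255	rs10850034	2.49E-05
12	NAA25	1.34E-02	7	rs17696736	1.93E-03	1.21E-04	105	rs17696736	1.13E-05
12	OS9	9.80E-05	2	rs799265	7.96E-06	1.38E-02	50	rs76809208	3.47E-03
14	NUDT14	2.29E-02	2	rs11625862	1.60E-02	3.33E-04	26	rs11625865	9.99E-05
19	PDE4C	4.54E-04	7	rs4808762	1.06E-06	1.78E-02	101	rs11667487	1.65E-03
19	SLC44A2	3.16E-04	4	rs8106664	1.78E-04	5.42E-03	142	rs7250421	5.95E-04
20	LIME1	8.20E-05	2	rs2427536	6.78E-05	8.91E-03	19	rs1056441	1.64E-03
20	RTEL1	1.76E-04	6	rs6011002	2.36E-04	6.07E-03	192	rs145832440	6.13E-04
20	RTEL1-TNFRSF6B	1.47E-04	6	rs6011002	2.36E-04	5.58E-03	205	rs145832440	6.13E-04
20	SLC2A4RG	8.60E-05	2	rs2427536	6.78E-05	1.02E-02	20	rs1056441	1.64E-03
20	ZBTB46	3.04E-03	12	rs6062314	8.26E-07	5.42E-03	302	rs150589984	2.18E-04
20	ZGPAT	1.46E-03	5	rs1151625	1.04E-04	5.93E-03	98	rs6011040	1.22E-03
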