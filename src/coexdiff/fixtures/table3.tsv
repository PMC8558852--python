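lncrna_id	lncrna_symbol	lncrna_log2fc	lncrna_adj_p	mrna_id	mrna_symbol	mrna_log2fc	mrna_adj_p	upregulated
ENSG00000180139	ACTA2-AS1	-2.51	1.53E-08	ENSG00000145936	KCNMB1	-2.79	2.84E-08	0
ENSG00000180139	ACTA2-AS1	-2.51	1.53E-08	ENSG00000196923	PDLIM7	-1.74	3.82E-06	0
ENSG00000180139	ACTA2-AS1	-2.51	1.53E-08	ENSG00000140682	TGFB1I1	-2.28	4.33E-07	0
ENSG00000180139	ACTA2-AS1	-2.51	1.53E-08	ENSG00000198467	TPM2	-2.55	7.30E-09	0
ENSG00000223774	NA	-3.09	3.41E-10	ENSG00000174099	MSRB3	-2.35	6.16E-09	0
ENSG00000223774	NA	-3.09	3.41E-10	ENSG00000072864	NDE1	-2.94	1.19E-10	0
ENSG00000230729	NA	-2.34	0.000161077	ENSG00000168913	ENHO	-1.95	0.002818634	0
ENSG00000230937	MIR205HG	-4.12	3.32E-06	ENSG00000186081	KRT5	-3.65	1.64E-06	0
ENSG00000234405	NA	-2.86	3.36E-05	ENSG00000172476	RAB40A	-2.53	0.000185962	0
ENSG00000234477	NA	-3.42	1.81E-05	ENSG00000108244	KRT23	-3.11	0.000196113	0
ENSG00000234638	NA	-3.26	6.33E-10	ENSG00000163017	ACTG2	-3.19	7.14E-11	0
ENSG00000249825	CTD-2201I18.1	1.84	0.000143879	ENSG00000113296	THBS4	2.22	0.000308678	1
ENSG00000255301	NA	1.37	3.50E-05	ENSG00000186907	RTN4RL2	1.48	2.89E-06	1
ENSG00000258451	NA	-1.80	4.42E-08	ENSG00000258818	RNASE4	-1.55	6.29E-08	0
ENSG00000259018	NA	-2.68	7.19E-10	ENSG00000100842	EFS	-2.58	2.68E-08	0
ENSG00000259172	NA	1.27	0.000139358	ENSG00000140479	PCSK6	1.30	4.98E-05	1
ENSG00000259780	NA	1.97	2.91E-08	ENSG00000167968	DNASE1L2	2.00	3.32E-06	1
ENSG00000260213	NA	1.88	8.23E-07	ENSG00000166451	CENPN	1.78	7.19E-06	1
ENSG00000261707	NA	-1.29	7.90E-12	ENSG00000140876	NUDT7	-1.07	1.13E-08	0
ENSG00000263065	NA	-3.47	2.78E-09	ENSG00000072864	NDE1	-2.94	1.19E-10	0
ENSG00000263065	NA	-3.47	2.78E-09	ENSG00000095637	SORBS1	-2.52	3.83E-09	0
ENSG00000263335	NA	-3.38	6.01E-10	ENSG00000095637	SORBS1	-2.52	3.83E-09	0
ENSG00000267577	NA	1.95	5.17E-06	ENSG00000167646	DNAAF3	2.14	1.06E-06	1
ENSG00000267601	NA	-1.75	2.90E-07	ENSG00000178404	CEP295NL	-1.48	9.32E-05	0
ENSG00000271894	NA	-2.84	3.66E-10	ENSG00000055813	CCDC85A	-2.70	3.07E-07	0
ENSG00000279047	NA	2.15	0.00010411	ENSG00000112852	PCDHB2	2.27	7.26E-06	1
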