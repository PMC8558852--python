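gene_id	symbol	biotype	log2fc	adj_p
ENSG00000136883	KIF12	mRNA	1.66	0.0024
ENSG00000196436	NPIPB15	mRNA	1.61	0.0092
ENSG00000244752	CRYBB2	mRNA	1.50	0.0024
ENSG00000182667	NTM	mRNA	1.42	0.0031
ENSG00000160973	FOXH1	mRNA	1.01	0.0060
ENSG00000104490	NCALD	mRNA	-1.05	0.0083
ENSG00000184058	TBX1	mRNA	-1.28	0.0031
ENSG00000198785	GRIN3A	mRNA	-1.53	0.0083
ENSG00000274767	AC243829.1	lncRNA	2.08	0.0003
ENSG00000259471	LINC01169	lncRNA	1.95	0.0016
ENSG00000268181	AC073188.6	lncRNA	1.91	0.0038
ENSG00000269978	AL359881.1	lncRNA	1.64	0.0038
ENSG00000232283	HSD17B3-AS1	lncRNA	1.49	0.0088
ENSG00000275476	AC009318.4	lncRNA	1.43	0.0016
ENSG00000271959	AC100803.4	lncRNA	1.29	0.0073
ENSG00000262188	LINC01978	lncRNA	1.25	0.0062
ENSG00000261159	AC112484.3	lncRNA	1.23	0.0003
ENSG00000262877	AC110285.2	lncRNA	1.20	0.0046
ENSG00000232850	PTGES2-AS1	lncRNA	1.20	0.0083
ENSG00000253629	AP000426.1	lncRNA	-1.08	0.0029
ENSG00000278936	AC244517.4	lncRNA	-1.08	0.0077
ENSG00000277232	GTSE1-DT	lncRNA	-1.09	0.0016
ENSG00000182366	FAM87A	lncRNA	-1.19	0.0005
ENSG00000250604	AC098679.1	lncRNA	-1.19	0.0005
ENSG00000261357	AC099518.2	lncRNA	-1.30	0.0069
ENSG00000279068	AC244517.6	lncRNA	-1.31	0.0046
ENSG00000249159	AC091965.1	lncRNA	-1.45	0.0088
ENSG00000279472	AC244517.8	lncRNA	-1.76	0.0003
ENSG00000278472	AC009268.2	lncRNA	-2.92	0.0080
ENSG00000271314	AL161729.2	lncRNA	-3.00	0.0027
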