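gene_id	symbol	biotype	chrom	start	end	strand
ENSG00000180139	ACTA2-AS1	lncRNA	chr1	20001	25000	-
ENSG00000223774	NA	lncRNA	chr1	60001	65000	-
ENSG00000230729	NA	lncRNA	chr1	100001	105000	-
ENSG00000230937	MIR205HG	lncRNA	chr1	140001	145000	-
ENSG00000234405	NA	lncRNA	chr1	180001	185000	-
ENSG00000234477	NA	lncRNA	chr1	220001	225000	-
ENSG00000234638	NA	lncRNA	chr1	260001	265000	-
ENSG00000249825	CTD-2201I18.1	lncRNA	chr5	103001	108000	-
ENSG00000255301	NA	lncRNA	chr1	300001	305000	-
ENSG00000258451	NA	lncRNA	chr1	340001	345000	-
ENSG00000259018	NA	lncRNA	chr1	380001	385000	-
ENSG00000259172	NA	lncRNA	chr15	203001	208000	-
ENSG00000259780	NA	lncRNA	chr1	420001	425000	-
ENSG00000260213	NA	lncRNA	chr1	460001	465000	-
ENSG00000261707	NA	lncRNA	chr1	500001	505000	-
ENSG00000263065	NA	lncRNA	chr1	540001	545000	-
ENSG00000263335	NA	lncRNA	chr1	580001	585000	-
ENSG00000267577	NA	lncRNA	chr1	620001	625000	-
ENSG00000267601	NA	lncRNA	chr1	660001	665000	-
ENSG00000271894	NA	lncRNA	chr1	700001	705000	-
ENSG00000279047	NA	lncRNA	chr1	740001	745000	-
ENSG00000145936	KCNMB1	mRNA	chr2	20001	25000	+
ENSG00000196923	PDLIM7	mRNA	chr2	60001	65000	+
ENSG00000140682	TGFB1I1	mRNA	chr2	100001	105000	+
ENSG00000198467	TPM2	mRNA	chr2	140001	145000	+
ENSG00000174099	MSRB3	mRNA	chr2	180001	185000	+
ENSG00000072864	NDE1	mRNA	chr2	220001	225000	+
ENSG00000168913	ENHO	mRNA	chr2	260001	265000	+
ENSG00000186081	KRT5	mRNA	chr2	300001	305000	+
ENSG00000172476	RAB40A	mRNA	chr2	340001	345000	+
ENSG00000108244	KRT23	mRNA	chr2	380001	385000	+
ENSG00000163017	ACTG2	mRNA	chr2	420001	425000	+
ENSG00000113296	THBS4	mRNA	chr5	100001	105000	+
ENSG00000186907	RTN4RL2	mRNA	chr2	460001	465000	+
ENSG00000258818	RNASE4	mRNA	chr2	500001	505000	+
ENSG00000100842	EFS	mRNA	chr2	540001	545000	+
ENSG00000140479	PCSK6	mRNA	chr15	200001	205000	+
ENSG00000167968	DNASE1L2	mRNA	chr2	580001	585000	+
ENSG00000166451	CENPN	mRNA	chr2	620001	625000	+
ENSG00000140876	NUDT7	mRNA	chr2	660001	665000	+
ENSG00000095637	SORBS1	mRNA	chr2	700001	705000	+
ENSG00000167646	DNAAF3	mRNA	chr2	740001	745000	+
ENSG00000178404	CEP295NL	mRNA	chr2	780001	785000	+
ENSG00000055813	CCDC85A	mRNA	chr2	820001	825000	+
ENSG00000112852	PCDHB2	mRNA	chr2	860001	865000	+
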