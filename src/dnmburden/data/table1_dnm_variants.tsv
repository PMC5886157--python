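family	chrom	pos	ref	alt	gene	exon	aa_change	exac_maf	cadd_phred	mutation_class
SLE0751	22	38336799	C	T	MICALL1	16	Arg852Cys	1.5e-4	35	TiCpG
SLE0496	3	53223122	G	A	PRKCD	16	Gly535Arg		34	TiCpG
SLE0679	12	57588368	C	T	LRP1	50	Arg2693Cys	8.3e-4	34	TiCpG
SLE0592	6	36260896	G	A	PNPLA1	3	Arg166His	5.8e-5	33	TiCpG
SLE0296	2	25457236	G	A	DNMT3A	19	Ala695Val		32	TiCpG
SLE0571	4	79512728	G	T	ANXA3	7	Ser145Ile		25.2	Tv
SLE0679	3	171431716	G	A	PLD1	9	Thr293Met	5.8e-5	25.1	TiCpG
SLE0411	5	179743769	C	T	GFPT2	12	Val383Met	2.6e-5	23.4	TiCpG
SLE0679	7	138968784	C	A	UBN2	15	Pro1045Thr		18.46	Tv
SLE0080	16	2812426	C	T	SRRM2	11	Arg633Cys		14.32	TiCpG
SLE0852	11	47611769	G	C	C1QTNF4	2	His198Gln		12.29	Tv
SLE0321	18	61621642	G	A	HMSD	3	Ala25Thr		9.732	Ti
SLE0390	12	32369376	G	C	BICD1	2	Val137Leu		8.673	Tv
SLE0321	1	35251125	C	G	GJB3	2	Asp254Glu		0.002	Tv
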