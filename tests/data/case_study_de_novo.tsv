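Chromosome	Coordinate	Reference allele	Sample allele	Gene symbol	Transcript ID	Nucleotide alteration	Amino acid alteration	SIFT	PolyPhen-2	PhyloP p-value	dbSNP ID	1000 Genomes frequency	Zygosity
12	81653434	A	G	PPFIA2	NM_001220473.2	c.133A>G	p.Val1241Ile	tolerated					het
2	99193000	G	T	INPP4A	NM_001134224	c.2855G>T	p.R952L	damaging	probably_damaging	0.002			het
19	5946520	G	A	RANBP3	NM_007320	c.985G>A	p.E329K	damaging	possibly_damaging	0.004			het
1	233134162	C	T	PCNXL2	NM_014801.3	c.5626C>T	p.Arg1876Cys	damaging	benign	0.01			het
16	2012584	C	T	RPS2	NM_002952.3	c.623C>T	p.Pro208Leu	damaging	benign	0.02			het
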