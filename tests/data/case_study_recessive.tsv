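Chromosome	Coordinate	Reference allele	Sample allele	Gene symbol	Transcript ID	Nucleotide alteration	Amino acid alteration	SIFT	PolyPhen-2	PhyloP p-value	dbSNP ID	1000 Genomes frequency	Zygosity
10	127477177	A	G	UROS	NM_000375	c.217T>C	p.C73R	damaging	probably_damaging	0.001	rs121908012	0.0001	hom
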