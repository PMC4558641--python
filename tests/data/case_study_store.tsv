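source	chrom	pos	ref	alt	gene	af	hemi_male_count	assertion
HGMD	10	127477177	A	G				CM900225
ClinVar	10	127477177	A	G				RCV000003948.2
dbSNP	10	127477177	A	G				rs121908012
1000 Genome	10	127477177	A	G		0.0001
OMIM					UROS			263700
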