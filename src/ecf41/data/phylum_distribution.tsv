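phylum	n_proteins	pct_proteins	n_species	pct_sequenced_species	n_genomes	n_sequenced_species
Actinobacteria	252	68	60	51	181	118
Proteobacteria	84	23	66	15	705	414
Firmicutes	15	4.0	10	2.5	404	182
Chloroflexi	11	2.9	3	60	15	5
Acidobacteria	4	1.1	4	67	6	6
Bacteriodetes	2	0.5	2	4.4	53	45
Cyanobacteria	2	0.5	2	6.3	44	32
Spirochaetes	1	0.3	1	5.6	23	18
Verrucomicrobia	1	0.3	1	25	4	4
Gemmatimonadetes	1	0.3	1	100	1	1
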