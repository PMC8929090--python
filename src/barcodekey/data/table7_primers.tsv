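# Seven wet-lab-validated Scutellaria species-specific primer pairs.
# annealing_tm is the empirical annealing temperature in deg C (metadata, not computed).
name	forward	reverse	product_size	annealing_tm	accession	locus	target_species
SL	TGCTTACCTGCTTCCACAGG	TCGGTGGCGACGTTATATGG	945	54	KM526800.1	CYC2B	S_indica_L
SP	GAAATTACTTTTAAATTCAT	GTAGTCTTTCCTAGACTTTA	173	42	KX060016.1	trnH-psbA	S_pekinensis_transitra
ST1	TTGTGGCATCACTAACCCCC	AGGGGTAGGCTGAACGTACT	491	54	MZ714561	atpI_0	S_indica_tsusimensis
ST2	CGCATTCCTCCAGCCTATGT	ATCACGGCAGTAGTGTGCAA	444	54	MZ714562	rbcL_3	S_indica_tsusimensis
SD1	ATAACTTCCCTCTAGACTTA	TGAATTTCAATTATTTTTTC	939	43	KT750009.1	-	S_barbata
SD2	ACCCTTGATTCGCACACTGA	TGAGGAAACGGACGTAAGCC	77	55	KX059898.1	psbK-psbI	S_barbata
SB	TCCCCAAAAAGTGGATCCCG	GGGCCTCATTGGTAAGTGCT	218	55	MF521633.1	-	S_baicalensis
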