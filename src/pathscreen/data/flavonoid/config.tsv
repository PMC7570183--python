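CHS	synthetic_CHS_baits.fasta	CHS_synthetic_1	CHS.residues.txt
STS	synthetic_STS_baits.fasta	STS_synthetic_1	
DFR	synthetic_DFR_baits.fasta	DFR_synthetic_1	DFR.residues.txt
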