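name	recognition	cut_offset
AluI	AGCT	2
AvaI	CYCGRG	1
BamHI	GGATCC	1
DraI	TTTAAA	3
EcoRI	GAATTC	1
EcoRV	GATATC	3
HaeIII	GGCC	2
HindIII	AAGCTT	1
HinfI	GANTC	1
KpnI	GGTACC	5
PaeI	GCATGC	5
PstI	CTGCAG	5
SacI	GAGCTC	5
SalI	GTCGAC	1
SmaI	CCCGGG	3
XbaI	TCTAGA	1
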