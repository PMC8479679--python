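# name	recognition site (IUPAC)
EcoRI	GAATTC
EcoRV	GATATC
BamHI	GGATCC
BglII	AGATCT
HindIII	AAGCTT
KpnI	GGTACC
NcoI	CCATGG
NdeI	CATATG
NheI	GCTAGC
NotI	GCGGCCGC
PstI	CTGCAG
PvuII	CAGCTG
SacI	GAGCTC
SalI	GTCGAC
ScaI	AGTACT
SmaI	CCCGGG
SpeI	ACTAGT
SphI	GCATGC
StuI	AGGCCT
XbaI	TCTAGA
XhoI	CTCGAG
ApaI	GGGCCC
AvrII	CCTAGG
MluI	ACGCGT
SnaBI	TACGTA
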