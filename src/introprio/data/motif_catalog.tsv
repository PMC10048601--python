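name	consensus	category
ARE	AAACCA	environmental_stress
DRE	RCCGAC	environmental_stress
LTR	CCGAAA	environmental_stress
MBS	CAACTG	environmental_stress
MBSI	AAAAAACCGGT	environmental_stress
GC-motif	CCCCCG	environmental_stress
TC-rich	ATTTTCTTCA	environmental_stress
WUN	AAATTTCCT	environmental_stress
CCAAT-box	CAACGG	environmental_stress
HSE	AGAANNTTCT	environmental_stress
ABRE	ACGTGKC	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
AuxRR-core	GGTCCAT	hormone
TGA-element	AACGAC	hormone
GARE	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TATC-box	TATCCCA	hormone
TCA-element	CCATCTTTTT	hormone
G-box	CACGTK	light
GT1-motif	GGTTAA	light
Box4	ATTAAT	light
CAT-box	GCCACT	developmental
O2-site	GATGAYRTGR	developmental
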