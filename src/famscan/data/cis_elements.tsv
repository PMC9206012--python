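# Canonical PlantCARE-style promoter cis-element consensi (IUPAC codes)
# mapped to functional classes. Editable; scanned on both strands.
name	consensus	functional_class
TATA-box	TATAAA	core
CAAT-box	CCAAT	core
ABRE	ACGTGGC	hormone
AuxRE	TGTCTC	hormone
TGA-element	AACGAC	hormone
GARE-motif	TCTGTTG	hormone
P-box	CCTTTTG	hormone
TCA-element	CCATCTTTTT	hormone
CGTCA-motif	CGTCA	hormone
TGACG-motif	TGACG	hormone
ABRE3a	TACGTG	hormone
SARE	TTCGACCATCTT	hormone
ARE	AAACCA	stress
MBS	CAACTG	stress
LTR	CCGAAA	stress
TC-rich_repeats	ATTCTCTAAC	stress
W-box	TTGACC	stress
DRE-core	RCCGAC	stress
G-box	CACGTG	growth
Box4	ATTAAT	growth
Skn-1_motif	GTCAT	growth
GCN4_motif	TGAGTCA	growth
RY-element	CATGCATG	growth
CAT-box	GCCACT	growth
circadian	CAANNNNATC	other
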