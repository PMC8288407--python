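# Canonical hematopoietic transcription factors (editable).
# One gene symbol per line; lines starting with '#' are ignored.
# Compiled from widely reported lineage-defining regulators of human
# hematopoiesis (HSPC, lymphoid, myeloid and erythroid programs).
RUNX1
TAL1
GATA2
GATA1
GATA3
KLF1
NFE2
SPI1
SPIB
CEBPA
CEBPB
CEBPD
CEBPE
IRF4
IRF8
PAX5
EBF1
TCF3
TCF4
TCF7
LEF1
BCL11A
BCL11B
PRDM1
XBP1
POU2F2
POU2AF1
ID2
ID3
IKZF1
IKZF3
MYB
MYC
FLI1
ERG
LMO2
LYL1
MEIS1
HOXA9
HOXB4
HLF
MECOM
GFI1
GFI1B
EGR1
EGR2
JUN
JUNB
FOS
FOSB
STAT1
STAT3
STAT4
STAT5A
STAT5B
TBX21
EOMES
RORA
RORC
FOXP3
FOXO1
NFKB1
REL
RELA
RELB
NOTCH1
RBPJ
ZEB2
KLF2
KLF4
NR4A1
NR4A2
MAF
MAFB
BATF
BATF3
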