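# Curated AIS (adolescent idiopathic scoliosis) literature gene panel, 56 symbols.
# SYNTHETIC STAND-IN: the original curated appendix list is not redistributable;
# this reconstruction keeps the ten symbols printed in the cohort's AIS-related
# rare-variant table and fills the panel with 46 genes reported as associated
# with AIS onset, severity or susceptibility in the published literature.
ARF1
MAGI1
TNIK
GC
FBN2
NT5DC1
IL6
CSMD1
PAX1
TBX1
LBX1
ADGRG6
BNC2
FBN1
COL11A1
COL11A2
COL1A1
COL1A2
COL2A1
COL5A2
SOX9
PAX3
TBX6
CHD7
POC5
EPHA4
SLC39A8
CELSR2
AKAP2
MATN1
MTNR1B
TPH1
LEPR
ESR1
ESR2
VDR
CALM1
IGF1
MEOX1
MEOX2
NUCKS1
IL17RC
CHL1
DSCAM
CNTNAP2
SOX6
CDH13
ABO
SNTG1
PTK7
CENPJ
POC1B
TTLL11
FLNB
HSPG2
ADIPOQ
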