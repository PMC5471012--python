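gene	exons
AKT1	2
ALK	23
APC	15
BRAF	11,15
CDH1	8,9,12
CTNNB1	2
EGFR	18,19,20,21
ERBB2	20
FBXW7	7,8,9,10,11
FGFR2	6
FOXL2	1
GNAQ	4,5,6
GNAS	6,8
KIT	9,11,13,17,18
KRAS	1,2,3,4
MAP2K1	2
MET	1,4,13,15,16,17,18,20
MSH6	5
NRAS	1,2,3,4
PDGFRA	11,13,17
PIK3CA	1,2,7,9,20
PTEN	1,2,3,4,5,6,7,9
SMAD4	8,11
SRC	10
STK11	1,4,6,8
TP53	2,3,4,5,6,7,8,9,10,11
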