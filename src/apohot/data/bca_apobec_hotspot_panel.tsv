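gene	protein_change	n_mutated
FGFR3	S249C	51
PIK3CA	E545K	47
ERBB2	S310F	27
PIK3CA	E542K	25
RXRA	S427F	19
TP53	E285K	17
TP53	R280T	15
KDM6A	Q555*	11
TBC1D12	c.-1G>A	11
C3orf70	S6L	10
RHOB	E172K	9
AHR	Q383H	8
LPAR6	F316F	8
TP53	Q331*	8
TP53	E271K	8
RARS2	R6C	7
SF3B1	E902K	7
TP53	R280K	7
ERBB3	E332K	6
MROH2B	E1109K	6
PIK3CA	E545Q	6
PPCS	S113L	6
STAG2	Q593*	6
ACSS3	S290L	5
CELSR3	E356K	5
KCNF1	E158K	5
PDE3A	L275L	5
PIK3CA	E726K	5
PLXNA2	E1480K	5
RHOB	E47K	5
TFPI2	R222C	5
TP53	K132N	5
CAMK2G	I132I	4
CELSR1	E1382K	4
EP300	Q1082*	4
ERBB4	E317K	4
FAM90A1	L251L	4
FURIN	R693W	4
KDM6A	S1061*	4
PBX2	E70K	4
RB1	Q217*	4
RREB1	Q392*	4
TP53	Q192*	4
TTC23L	Q263Q	4
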