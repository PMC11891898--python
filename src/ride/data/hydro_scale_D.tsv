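# variant=D temperature=310.15 viscosity=0.275 radii=united
# AA	C
ALA	0.0752293
ARG	0.0647368
ASN	0.065475
ASP	0.0847459
CYS	0.0587268
GLN	0.0594599
GLU	0.0714969
GLY	0.0767016
HIS	0.0520394
ILE	0.0612605
LEU	0.0550447
LYS	0.0681776
MET	0.0457476
PHE	0.0480965
PRO	0.0884844
SER	0.0664362
THR	0.0673259
TRP	0.0431261
TYR	0.0506833
VAL	0.0722509
TERM_CAPPED	0.0653812
TERM_ZWIT	0.0764618
SESA_TERM	0.94692
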