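# variant=M temperature=310.15 viscosity=0.275 radii=united
# AA	C
ALA	0.0850597
ARG	0.0964581
ASN	0.109001
ASP	0.133268
CYS	0.0905834
GLN	0.0918337
GLU	0.121862
GLY	0.0665751
HIS	0.102879
ILE	0.0885319
LEU	0.0946358
LYS	0.102545
MET	0.0864687
PHE	0.0849371
PRO	0.0779862
SER	0.113682
THR	0.0964773
TRP	0.0920942
TYR	0.0949499
VAL	0.0947309
TERM_CAPPED	0.0653812
TERM_ZWIT	0.117906
SESA_TERM	0.94692
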