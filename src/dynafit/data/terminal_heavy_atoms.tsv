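# Terminal (side-chain tip) non-hydrogen reference atoms per amino acid.
# residue_name<TAB>comma-separated atom names
ALA	CB
ARG	NH1,NH2
ASN	OD1,ND2
ASP	OD1,OD2
CYS	SG
CYX	SG
GLN	OE1,NE2
GLU	OE1,OE2
GLH	OE1,OE2
ASH	OD1,OD2
GLY	CA
HIS	ND1,NE2
HID	ND1,NE2
HIE	ND1,NE2
HIP	ND1,NE2
ILE	CD1
LEU	CD1,CD2
LYS	NZ
LYN	NZ
MET	CE
PHE	CZ
PRO	CG
SER	OG
THR	OG1,CG2
TRP	CH2
TYR	OH
VAL	CG1,CG2
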