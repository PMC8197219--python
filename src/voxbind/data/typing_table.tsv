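# Surface atom-type assignments: residue <TAB> atom <TAB> code
# Codes follow the 3-code grammar: element / hybridisation-context
# (2=sp2, 3=sp3, R=aromatic, C=conjugated) / polarity (N=nonpolar,
# P=polar, V=variable, C=charged).  Backbone atoms are listed under
# the pseudo-residue "*" and apply to every standard amino acid.
*	N	NCP
*	CA	C3P
*	C	CCP
*	O	OCP
*	OXT	OCC
ALA	CB	C3N
ARG	CB	C3N
ARG	CG	C3N
ARG	CD	C3P
ARG	NE	NCC
ARG	CZ	CCP
ARG	NH1	NCC
ARG	NH2	NCC
ASN	CB	C3N
ASN	CG	CCP
ASN	OD1	OCP
ASN	ND2	NCP
ASP	CB	C3N
ASP	CG	CCP
ASP	OD1	OCC
ASP	OD2	OCC
CYS	CB	C3N
CYS	SG	S3N
GLN	CB	C3N
GLN	CG	C3N
GLN	CD	CCP
GLN	OE1	OCP
GLN	NE2	NCP
GLU	CB	C3N
GLU	CG	C3N
GLU	CD	CCP
GLU	OE1	OCC
GLU	OE2	OCC
HIS	CB	C3N
HIS	CG	CRP
HIS	ND1	NRV
HIS	CD2	CRP
HIS	CE1	CRP
HIS	NE2	NRV
ILE	CB	C3N
ILE	CG1	C3N
ILE	CG2	C3N
ILE	CD1	C3N
LEU	CB	C3N
LEU	CG	C3N
LEU	CD1	C3N
LEU	CD2	C3N
LYS	CB	C3N
LYS	CG	C3N
LYS	CD	C3N
LYS	CE	C3P
LYS	NZ	N3C
MET	CB	C3N
MET	CG	C3N
MET	SD	S3N
MET	CE	C3N
PHE	CB	C3N
PHE	CG	CRN
PHE	CD1	CRN
PHE	CD2	CRN
PHE	CE1	CRN
PHE	CE2	CRN
PHE	CZ	CRN
PRO	CB	C3N
PRO	CG	C3N
PRO	CD	C3P
SER	CB	C3P
SER	OG	O3P
THR	CB	C3P
THR	OG1	O3P
THR	CG2	C3N
TRP	CB	C3N
TRP	CG	CRN
TRP	CD1	CRP
TRP	CD2	CRN
TRP	NE1	NRV
TRP	CE2	CRP
TRP	CE3	CRN
TRP	CZ2	CRN
TRP	CZ3	CRN
TRP	CH2	CRN
TYR	CB	C3N
TYR	CG	CRN
TYR	CD1	CRN
TYR	CD2	CRN
TYR	CE1	CRN
TYR	CE2	CRN
TYR	CZ	CRP
TYR	OH	O3P
VAL	CB	C3N
VAL	CG1	C3N
VAL	CG2	C3N
# Hetero metals (kept only when parsing retains HETATM records)
ZN	ZN	MET
MG	MG	MET
MN	MN	MET
FE	FE	MET
NA	NA	MET
K	K	MET
CA	CA	MET
NI	NI	MET
CU	CU	MET
CO	CO	MET
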