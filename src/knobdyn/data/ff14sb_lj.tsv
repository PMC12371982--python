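# Lennard-Jones parameters, AMBER convention (r_min/2 in A, epsilon in kcal/mol).
# Heavy atoms of the 20 standard residues are mapped exactly; hydrogens are
# covered by name-pattern rules at the end of the table (approximate types).
# Exact (residue, atom) rows take precedence over wildcard rows; wildcard
# rows apply in file order.
residue_name	atom_name	type	r_min_half_A	epsilon_kcal
ALA	N	N	1.8240	0.1700
ALA	CA	CX	1.9080	0.1094
ALA	C	C	1.9080	0.0860
ALA	O	O	1.6612	0.2100
ALA	OXT	O2	1.6612	0.2100
ALA	CB	CT	1.9080	0.1094
ARG	N	N	1.8240	0.1700
ARG	CA	CX	1.9080	0.1094
ARG	C	C	1.9080	0.0860
ARG	O	O	1.6612	0.2100
ARG	OXT	O2	1.6612	0.2100
ARG	CB	CT	1.9080	0.1094
ARG	CG	CT	1.9080	0.1094
ARG	CD	CT	1.9080	0.1094
ARG	NE	N2	1.8240	0.1700
ARG	CZ	CA	1.9080	0.0860
ARG	NH1	N2	1.8240	0.1700
ARG	NH2	N2	1.8240	0.1700
ASN	N	N	1.8240	0.1700
ASN	CA	CX	1.9080	0.1094
ASN	C	C	1.9080	0.0860
ASN	O	O	1.6612	0.2100
ASN	OXT	O2	1.6612	0.2100
ASN	CB	CT	1.9080	0.1094
ASN	CG	C	1.9080	0.0860
ASN	OD1	O	1.6612	0.2100
ASN	ND2	N	1.8240	0.1700
ASP	N	N	1.8240	0.1700
ASP	CA	CX	1.9080	0.1094
ASP	C	C	1.9080	0.0860
ASP	O	O	1.6612	0.2100
ASP	OXT	O2	1.6612	0.2100
ASP	CB	CT	1.9080	0.1094
ASP	CG	C	1.9080	0.0860
ASP	OD1	O2	1.6612	0.2100
ASP	OD2	O2	1.6612	0.2100
CYS	N	N	1.8240	0.1700
CYS	CA	CX	1.9080	0.1094
CYS	C	C	1.9080	0.0860
CYS	O	O	1.6612	0.2100
CYS	OXT	O2	1.6612	0.2100
CYS	CB	CT	1.9080	0.1094
CYS	SG	SH	2.0000	0.2500
GLN	N	N	1.8240	0.1700
GLN	CA	CX	1.9080	0.1094
GLN	C	C	1.9080	0.0860
GLN	O	O	1.6612	0.2100
GLN	OXT	O2	1.6612	0.2100
GLN	CB	CT	1.9080	0.1094
GLN	CG	CT	1.9080	0.1094
GLN	CD	C	1.9080	0.0860
GLN	OE1	O	1.6612	0.2100
GLN	NE2	N	1.8240	0.1700
GLU	N	N	1.8240	0.1700
GLU	CA	CX	1.9080	0.1094
GLU	C	C	1.9080	0.0860
GLU	O	O	1.6612	0.2100
GLU	OXT	O2	1.6612	0.2100
GLU	CB	CT	1.9080	0.1094
GLU	CG	CT	1.9080	0.1094
GLU	CD	C	1.9080	0.0860
GLU	OE1	O2	1.6612	0.2100
GLU	OE2	O2	1.6612	0.2100
GLY	N	N	1.8240	0.1700
GLY	CA	CX	1.9080	0.1094
GLY	C	C	1.9080	0.0860
GLY	O	O	1.6612	0.2100
GLY	OXT	O2	1.6612	0.2100
HIS	N	N	1.8240	0.1700
HIS	CA	CX	1.9080	0.1094
HIS	C	C	1.9080	0.0860
HIS	O	O	1.6612	0.2100
HIS	OXT	O2	1.6612	0.2100
HIS	CB	CT	1.9080	0.1094
HIS	CG	CC	1.9080	0.0860
HIS	ND1	NB	1.8240	0.1700
HIS	CD2	CW	1.9080	0.0860
HIS	CE1	CR	1.9080	0.0860
HIS	NE2	NA	1.8240	0.1700
ILE	N	N	1.8240	0.1700
ILE	CA	CX	1.9080	0.1094
ILE	C	C	1.9080	0.0860
ILE	O	O	1.6612	0.2100
ILE	OXT	O2	1.6612	0.2100
ILE	CB	CT	1.9080	0.1094
ILE	CG1	CT	1.9080	0.1094
ILE	CG2	CT	1.9080	0.1094
ILE	CD1	CT	1.9080	0.1094
LEU	N	N	1.8240	0.1700
LEU	CA	CX	1.9080	0.1094
LEU	C	C	1.9080	0.0860
LEU	O	O	1.6612	0.2100
LEU	OXT	O2	1.6612	0.2100
LEU	CB	CT	1.9080	0.1094
LEU	CG	CT	1.9080	0.1094
LEU	CD1	CT	1.9080	0.1094
LEU	CD2	CT	1.9080	0.1094
LYS	N	N	1.8240	0.1700
LYS	CA	CX	1.9080	0.1094
LYS	C	C	1.9080	0.0860
LYS	O	O	1.6612	0.2100
LYS	OXT	O2	1.6612	0.2100
LYS	CB	CT	1.9080	0.1094
LYS	CG	CT	1.9080	0.1094
LYS	CD	CT	1.9080	0.1094
LYS	CE	CT	1.9080	0.1094
LYS	NZ	N3	1.8240	0.1700
MET	N	N	1.8240	0.1700
MET	CA	CX	1.9080	0.1094
MET	C	C	1.9080	0.0860
MET	O	O	1.6612	0.2100
MET	OXT	O2	1.6612	0.2100
MET	CB	CT	1.9080	0.1094
MET	CG	CT	1.9080	0.1094
MET	SD	S	2.0000	0.2500
MET	CE	CT	1.9080	0.1094
PHE	N	N	1.8240	0.1700
PHE	CA	CX	1.9080	0.1094
PHE	C	C	1.9080	0.0860
PHE	O	O	1.6612	0.2100
PHE	OXT	O2	1.6612	0.2100
PHE	CB	CT	1.9080	0.1094
PHE	CG	CA	1.9080	0.0860
PHE	CD1	CA	1.9080	0.0860
PHE	CD2	CA	1.9080	0.0860
PHE	CE1	CA	1.9080	0.0860
PHE	CE2	CA	1.9080	0.0860
PHE	CZ	CA	1.9080	0.0860
PRO	N	N	1.8240	0.1700
PRO	CA	CX	1.9080	0.1094
PRO	C	C	1.9080	0.0860
PRO	O	O	1.6612	0.2100
PRO	OXT	O2	1.6612	0.2100
PRO	CB	CT	1.9080	0.1094
PRO	CG	CT	1.9080	0.1094
PRO	CD	CT	1.9080	0.1094
SER	N	N	1.8240	0.1700
SER	CA	CX	1.9080	0.1094
SER	C	C	1.9080	0.0860
SER	O	O	1.6612	0.2100
SER	OXT	O2	1.6612	0.2100
SER	CB	CT	1.9080	0.1094
SER	OG	OH	1.7210	0.2104
THR	N	N	1.8240	0.1700
THR	CA	CX	1.9080	0.1094
THR	C	C	1.9080	0.0860
THR	O	O	1.6612	0.2100
THR	OXT	O2	1.6612	0.2100
THR	CB	CT	1.9080	0.1094
THR	OG1	OH	1.7210	0.2104
THR	CG2	CT	1.9080	0.1094
TRP	N	N	1.8240	0.1700
TRP	CA	CX	1.9080	0.1094
TRP	C	C	1.9080	0.0860
TRP	O	O	1.6612	0.2100
TRP	OXT	O2	1.6612	0.2100
TRP	CB	CT	1.9080	0.1094
TRP	CG	C*	1.9080	0.0860
TRP	CD1	CW	1.9080	0.0860
TRP	CD2	CB	1.9080	0.0860
TRP	NE1	NA	1.8240	0.1700
TRP	CE2	CN	1.9080	0.0860
TRP	CE3	CA	1.9080	0.0860
TRP	CZ2	CA	1.9080	0.0860
TRP	CZ3	CA	1.9080	0.0860
TRP	CH2	CA	1.9080	0.0860
TYR	N	N	1.8240	0.1700
TYR	CA	CX	1.9080	0.1094
TYR	C	C	1.9080	0.0860
TYR	O	O	1.6612	0.2100
TYR	OXT	O2	1.6612	0.2100
TYR	CB	CT	1.9080	0.1094
TYR	CG	CA	1.9080	0.0860
TYR	CD1	CA	1.9080	0.0860
TYR	CD2	CA	1.9080	0.0860
TYR	CE1	CA	1.9080	0.0860
TYR	CE2	CA	1.9080	0.0860
TYR	CZ	C	1.9080	0.0860
TYR	OH	OH	1.7210	0.2104
VAL	N	N	1.8240	0.1700
VAL	CA	CX	1.9080	0.1094
VAL	C	C	1.9080	0.0860
VAL	O	O	1.6612	0.2100
VAL	OXT	O2	1.6612	0.2100
VAL	CB	CT	1.9080	0.1094
VAL	CG1	CT	1.9080	0.1094
VAL	CG2	CT	1.9080	0.1094
SER	HG	HO	0.0001	0.0000
THR	HG1	HO	0.0001	0.0000
TYR	HH	HO	0.0001	0.0000
CYS	HG	HS	0.6000	0.0157
LYS	HZ1	H	0.6000	0.0157
LYS	HZ2	H	0.6000	0.0157
LYS	HZ3	H	0.6000	0.0157
ARG	HE	H	0.6000	0.0157
ARG	HH11	H	0.6000	0.0157
ARG	HH12	H	0.6000	0.0157
ARG	HH21	H	0.6000	0.0157
ARG	HH22	H	0.6000	0.0157
ASN	HD21	H	0.6000	0.0157
ASN	HD22	H	0.6000	0.0157
GLN	HE21	H	0.6000	0.0157
GLN	HE22	H	0.6000	0.0157
HIS	HD1	H	0.6000	0.0157
HIS	HE2	H	0.6000	0.0157
TRP	HE1	H	0.6000	0.0157
PHE	HD1	HA	1.4590	0.0150
PHE	HD2	HA	1.4590	0.0150
PHE	HE1	HA	1.4590	0.0150
PHE	HE2	HA	1.4590	0.0150
PHE	HZ	HA	1.4590	0.0150
TYR	HD1	HA	1.4590	0.0150
TYR	HD2	HA	1.4590	0.0150
TYR	HE1	HA	1.4590	0.0150
TYR	HE2	HA	1.4590	0.0150
TRP	HD1	HA	1.4590	0.0150
TRP	HE3	HA	1.4590	0.0150
TRP	HZ2	HA	1.4590	0.0150
TRP	HZ3	HA	1.4590	0.0150
TRP	HH2	HA	1.4590	0.0150
HIS	HD2	HA	1.4590	0.0150
HIS	HE1	HA	1.4590	0.0150
*	H	H	0.6000	0.0157
*	H1	H	0.6000	0.0157
*	H2	H	0.6000	0.0157
*	H3	H	0.6000	0.0157
*	HA*	H1	1.3870	0.0157
*	HB*	HC	1.4870	0.0157
*	HG*	HC	1.4870	0.0157
*	HD*	HC	1.4870	0.0157
*	HE*	HC	1.4870	0.0157
*	HZ*	HC	1.4870	0.0157
*	HH*	HC	1.4870	0.0157
*	H*	HC	1.4870	0.0157
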