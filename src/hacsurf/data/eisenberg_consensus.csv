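# Normalized consensus hydrophobicity scale (Eisenberg et al. 1984).
# Dimensionless; positive = hydrophobic. Max = Ile, min = Arg.
resname,hydrophobicity
ILE,0.73
PHE,0.61
VAL,0.54
LEU,0.53
TRP,0.37
MET,0.26
ALA,0.25
GLY,0.16
CYS,0.04
TYR,0.02
PRO,-0.07
THR,-0.18
SER,-0.26
HIS,-0.40
GLU,-0.62
ASN,-0.64
GLN,-0.69
ASP,-0.72
LYS,-1.10
ARG,-1.76
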