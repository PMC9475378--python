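# name: black-mould
# resolution: residue
# normalized: true
# provenance: Black & Mould 1991, Rekker fragment coefficients; normalized (GLY=0, mean h^2=1)
ALA 0.37
ARG -1.52
ASN -0.79
ASP -1.43
CYS 0.55
GLN -0.76
GLU -1.40
GLY 0.00
HIS -1.00
ILE 1.34
LEU 1.34
LYS -0.67
MET 0.73
PHE 1.52
PRO 0.64
SER -0.43
THR -0.15
TRP 1.16
TYR 1.16
VAL 1.00
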