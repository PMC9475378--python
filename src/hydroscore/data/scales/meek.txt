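# name: meek
# resolution: residue
# normalized: true
# provenance: Meek 1980 RP-HPLC retention coefficients at pH 7.4; normalized (GLY=0, mean h^2=1)
ALA 0.07
ARG 0.11
ASN 0.11
ASP -1.08
CYS -0.90
GLN -0.63
GLU -2.23
GLY 0.00
HIS -0.46
ILE 1.83
LEU 1.16
LYS 0.01
MET 0.63
PHE 1.74
PRO 0.80
SER 0.16
THR 0.36
TRP 1.96
TYR 0.80
VAL 0.36
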