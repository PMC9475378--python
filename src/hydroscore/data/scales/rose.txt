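# name: rose
# resolution: residue
# normalized: true
# provenance: Rose et al. 1985 mean fractional area loss on folding; normalized (GLY=0, mean h^2=1)
ALA 0.18
ARG -0.71
ASN -0.80
ASP -0.89
CYS 1.69
GLN -0.89
GLU -0.89
GLY 0.00
HIS 0.53
ILE 1.42
LEU 1.16
LYS -1.78
MET 1.16
PHE 1.42
PRO -0.71
SER -0.53
THR -0.18
TRP 1.16
TYR 0.36
VAL 1.25
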