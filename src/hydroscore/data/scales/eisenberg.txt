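# name: eisenberg
# resolution: residue
# normalized: true
# provenance: Eisenberg et al. 1984 consensus scale; normalized (GLY=0, mean h^2=1)
ALA 0.15
ARG -3.09
ASN -1.29
ASP -1.42
CYS -0.19
GLN -1.37
GLU -1.26
GLY 0.00
HIS -0.90
ILE 0.92
LEU 0.60
LYS -2.03
MET 0.16
PHE 0.73
PRO -0.37
SER -0.68
THR -0.55
TRP 0.34
TYR -0.23
VAL 0.61
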