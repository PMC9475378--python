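# name: bandyopadhyay-mehler
# resolution: residue
# normalized: true
# provenance: Bandyopadhyay & Mehler 2008, local-environment Rekker coefficients; normalized (GLY=0, mean h^2=1)
ALA 0.75
ARG -0.02
ASN -0.16
ASP -0.50
CYS 2.60
GLN -0.11
GLU -0.54
GLY 0.00
HIS 0.57
ILE 2.19
LEU 1.97
LYS -0.90
MET 1.22
PHE 1.92
PRO 0.72
SER 0.11
THR 0.47
TRP 1.51
TYR 1.36
VAL 1.88
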