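# name: miyazawa
# resolution: residue
# normalized: true
# provenance: Miyazawa & Jernigan 1985 contact-energy / surface-accessibility scale; normalized (GLY=0, mean h^2=1)
ALA 0.40
ARG -0.15
ASN -0.37
ASP -0.43
CYS 1.65
GLN -0.29
GLU -0.40
GLY 0.00
HIS 0.30
ILE 2.08
LEU 1.91
LYS -0.74
MET 2.14
PHE 2.18
PRO -0.29
SER -0.19
THR 0.00
TRP 1.52
TYR 0.68
VAL 1.51
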