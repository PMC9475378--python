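# name: wimley-white
# resolution: residue
# normalized: true
# provenance: Wimley & White 1996 interface scale (water to POPC interface); normalized (GLY=0, mean h^2=1)
ALA -0.20
ARG -0.41
ASN -0.51
ASP -1.53
CYS 0.31
GLN -0.71
GLU -2.51
GLY 0.00
HIS -0.20
ILE 0.35
LEU 0.71
LYS -0.59
MET 0.30
PHE 1.43
PRO -0.55
SER -0.15
THR -0.16
TRP 2.33
TYR 1.19
VAL -0.08
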