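# name: jain
# resolution: residue
# normalized: true
# provenance: Jain et al. 2017 HIC retention derived scale; normalized (GLY=0, mean h^2=1)
ALA 0.06
ARG -0.32
ASN 0.13
ASP -0.43
CYS 0.55
GLN 0.46
GLU -0.72
GLY 0.00
HIS 0.03
ILE 1.54
LEU 1.54
LYS -1.07
MET 0.49
PHE 2.48
PRO 0.44
SER 0.07
THR 0.16
TRP 2.81
TYR 1.84
VAL 0.97
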