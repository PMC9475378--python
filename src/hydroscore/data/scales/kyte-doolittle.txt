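# name: kyte-doolittle
# resolution: residue
# normalized: true
# provenance: Kyte & Doolittle 1982 hydropathy; normalized (GLY=0, mean h^2=1)
ALA 0.76
ARG -1.41
ASN -1.06
ASP -1.06
CYS 1.00
GLN -1.06
GLU -1.06
GLY 0.00
HIS -0.96
ILE 1.68
LEU 1.44
LYS -1.20
MET 0.79
PHE 1.10
PRO -0.41
SER -0.14
THR -0.10
TRP -0.17
TYR -0.31
VAL 1.58
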