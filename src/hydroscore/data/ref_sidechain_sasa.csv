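residue,area,provenance
ALA,58.764,"extended GXG host, probe 1.4 A, 960 points"
ARG,207.174,"extended GXG host, probe 1.4 A, 960 points"
ASN,115.595,"extended GXG host, probe 1.4 A, 960 points"
ASP,110.172,"extended GXG host, probe 1.4 A, 960 points"
CYS,94.924,"extended GXG host, probe 1.4 A, 960 points"
GLN,155.230,"extended GXG host, probe 1.4 A, 960 points"
GLU,143.602,"extended GXG host, probe 1.4 A, 960 points"
GLY,35.838,unused by default (GLY has no side-chain atoms)
HIS,151.508,"extended GXG host, probe 1.4 A, 960 points"
ILE,148.652,"extended GXG host, probe 1.4 A, 960 points"
LEU,136.813,"extended GXG host, probe 1.4 A, 960 points"
LYS,160.829,"extended GXG host, probe 1.4 A, 960 points"
MET,155.531,"extended GXG host, probe 1.4 A, 960 points"
PHE,176.347,"extended GXG host, probe 1.4 A, 960 points"
PRO,120.194,"extended GXG host, probe 1.4 A, 960 points"
SER,76.776,"extended GXG host, probe 1.4 A, 960 points"
THR,101.058,"extended GXG host, probe 1.4 A, 960 points"
TRP,226.292,"extended GXG host, probe 1.4 A, 960 points"
TYR,193.975,"extended GXG host, probe 1.4 A, 960 points"
VAL,117.070,"extended GXG host, probe 1.4 A, 960 points"
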