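"""Score a synthetic peptide with all four hydrophobicity methods.

Builds an extended Gly-Ala-Val-Leu-Trp peptide (no input files needed), assigns
the Kyte-Doolittle and Wildman-Crippen scales, and prints the direct surface
score, positive surface score, SAP, and Heiden score.  Surface scores are in
units of hydrophobicity x Angstrom^2; SAP is dimensionless; larger means a more
hydrophobic surface.
"""

import hydroscore as hs

peptide = hs.make_ideal_peptide("GAVLW", seed=11).structure
print(f"peptide {peptide.label}: {len(peptide)} atoms, "
      f"{len(peptide.residues())} residues")

table = hs.score_table([peptide], ["kyte-doolittle", "crippen"])
for row in table.itertuples():
    print(f"  {row.scale:16s} {row.method:9s} {row.score:10.2f}")

print("\nThe Heiden score is an area-weighted sum over hydrophobic surface "
      "patches;\nthe Trp side chain dominates all four scores for this sequence.")
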