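# hydroscore

Structure-based surface-hydrophobicity scoring for antibodies and other
proteins.

Surface hydrophobicity drives aggregation, poor solubility, and fast clearance
of therapeutic antibodies, and is routinely measured by hydrophobic interaction
chromatography (HIC).  `hydroscore` computes in-silico hydrophobicity scores
from a 3D structure (a crystal structure or homology model of an Fv/Fab
fragment in PDB format) so that candidate molecules can be ranked before any
wet-lab work, and provides the benchmarking harness to correlate those scores
with experimental HIC retention times.

## What it computes

Given per-atom hydrophobicity values *h<sub>i</sub>* assigned from a scale, and
per-atom solvent-accessible surface areas *A<sub>i</sub>* (Shrake–Rupley, probe
1.4 Å):

* **Direct surface score** — S<sub>surf</sub> = Σ<sub>i</sub> h<sub>i</sub>·A<sub>i</sub>
  over all atoms: the whole surface is desolvated on binding.
* **Positive surface score** — the same with negative *h* set to zero: only the
  hydrophobic surface regions are desolvated, which matches the physics of HIC
  more closely.
* **Spatial aggregation propensity (SAP)** — per atom *i*,
  SAP<sub>i</sub> = Σ<sub>j ∈ side chain, r<sub>ij</sub> &lt; R</sub>
  (A<sub>j</sub>/A<sub>j</sub><sup>res</sup>)·h<sub>j</sub> with cutoff
  R = 5 Å and the mean side-chain exposure A<sub>j</sub><sup>res</sup> of the
  free residue as the reference; the score is Σ<sub>i</sub> max(SAP<sub>i</sub>, 0).
* **Heiden (MLP) score** — a solvent-excluded surface mesh is built from a
  probe-distance grid (marching cubes at the 1.4 Å level); each vertex *k*
  carries the molecular lipophilicity potential
  MLP<sub>k</sub> = Σ<sub>j</sub> g(r<sub>jk</sub>)h<sub>j</sub> / Σ<sub>j</sub> g(r<sub>jk</sub>)
  with the logistic weight g(r) = [exp(α(r−R/2))+1]<sup>−1</sup> (α = 1.5 Å⁻¹,
  R = 5 Å); the score is Σ<sub>k</sub> max(MLP<sub>k</sub>, 0)·A<sub>k</sub>.

Eleven hydrophobicity scales ship with the package: nine residue-level scales
(Bandyopadhyay–Mehler, Black–Mould, Eisenberg, Kyte–Doolittle, Meek, Rose,
Wimley–White, Jain, Miyazawa), stored normalized so that Gly = 0 and the
variance over the 20 residues is 1 with hydrophobic residues positive, and two
atomic scales (Wildman–Crippen logP contributions, with amine-type hydrogens
on the aromatic nitrogens of Trp/His, and Eisenberg–McLachlan atomic solvation
parameters).  `normalize_scale` applies the same normalization to any
user-supplied scale.

Scores from boosted-MD frame ensembles can be averaged with second-order
cumulant reweighting of the boost energy, and `pearson_benchmark` correlates
any score table against experimental retention data per (scale, method).

## Worked example

```python
import hydroscore as hs

peptide = hs.make_ideal_peptide("GAVLW", seed=11).structure   # 79 atoms
table = hs.score_table([peptide], ["kyte-doolittle", "crippen"])
print(table)
```

prints (see `examples/score_peptide.py`):

```
  kyte-doolittle   surf          501.81
  kyte-doolittle   pos-surf      557.50
  kyte-doolittle   sap            81.07
  kyte-doolittle   heiden        357.92
  crippen          surf           69.82
  crippen          pos-surf      110.02
  crippen          sap            10.51
  crippen          heiden         23.26
```

Surface scores are in hydrophobicity·Å² (the scales are dimensionless), SAP is
dimensionless, and larger always means a more hydrophobic surface; `pos-surf`
exceeds `surf` because the hydrophilic (negative) contributions are clamped
rather than subtracted.  The other scripts in `examples/` demonstrate SES
meshing with per-vertex MLP export (`surface_mesh.py`), benchmarking against
retention data (`benchmark_hic.py`), and ensemble reweighting
(`ensemble_average.py`).

The same pipeline is available from the shell:

```bash
hydroscore scales list
hydroscore score --pdb fv.pdb --scale jain --method pos-surf --out scores.csv
hydroscore bench --scores scores.csv --hic hic.csv --out report/
hydroscore surface --pdb fv.pdb --scale crippen --out fv.ply
```

where `hic.csv` has columns `id,retention`.

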