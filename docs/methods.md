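# Methods

This note documents the models implemented in `hydroscore`, the numerical
choices behind them, and what the synthetic fixtures do and do not establish
about real antibody structures.

## Hydrophobicity scales and normalization

Residue scales from the literature use incompatible units (transfer free
energies, retention coefficients, burial fractions).  The packaged registry
stores them on a common footing: values are shifted so glycine is exactly zero
and divided by the population standard deviation of the 20 values, so each
scale has unit variance about its mean, with the overall sign chosen so that
hydrophobic residues are positive.  The sign rule is operationalized as: flip
if the mean over Ile/Leu/Phe/Val is negative.  Note that the variance is taken
about the *mean* of the values, not about the glycine anchor — the two differ
whenever the scale's mean is far from its glycine value, and only the former
recomputes to 1.00 ± 0.01 across all nine packaged scales.  `normalize_scale`
is idempotent up to printing precision and invariant to affine changes of the
raw input.

Histidine protonation variants (HID/HIE/HIP and the HSD/HSE dialects) all
receive the HIS value of a residue scale; the registry supports explicit
per-variant entries but ships none.  CYX folds to CYS and MSE to MET.

## Atomic scales

The Wildman–Crippen table assigns every (residue, atom-name) pair a logP
contribution.  It was generated once (`scripts/build_atom_tables.py`) by typing
Gly-X-Gly host tripeptides with RDKit's Crippen implementation — the Gly host
provides a mid-chain amide context for X — plus free amino acids for the
terminal-only atoms (H1/H2/H3, OXT, HXT), and histidine tautomers built
explicitly (HID, HIE, HIP; the canonical HIS entry covers the union of their
atom names so that any protonation dialect resolves).  Hydrogens bound to the
aromatic nitrogens of Trp and His carry the amine-class value (H3, +0.2142)
rather than the alcohol-class value, matching the chemistry of an aromatic
N–H.  The table is frozen as packaged CSV so typing never depends on RDKit at
run time; alternate hydrogen nomenclatures (HN for H, HT1 for H1, ...) resolve
through a synonym map and unresolvable names are errors, never silent zeros.

The Eisenberg–McLachlan scale is a five-class atomic solvation parameter set
(kcal·mol⁻¹·Å⁻²): C +0.016, neutral N/O −0.006, carboxylate O −0.024, charged
N −0.050, S +0.021.  The original parameterization is united-atom, so
hydrogens are assigned zero; charged classes are applied to Asp/Glu
carboxylates, OXT, Lys NZ, the Arg guanidinium nitrogens, and the HIP ring
nitrogens.

## Solvent-accessible surface area

Shrake–Rupley quadrature with a deterministic golden-spiral point set
(default 960 points; the isolated-sphere area is then exact and occluded
geometries converge as 1/n).  The probe radius defaults to 1.4 Å everywhere, a
water-sized probe.  Van der Waals radii are Bondi by element; hydrogens are
retained and participate in all surfaces (`strip_hydrogens` exists for
sensitivity checks).  The KD-tree neighbour search is exactly equivalent to
the all-pairs evaluation (`all_pairs=True`), which the tests assert.  With a
fixed quadrature sphere, per-atom areas are reproducible and translation
invariant to machine precision but orientation dependent at the level of one
point's area share (4πR²/n) — an intrinsic property of the algorithm, not an
implementation defect.

The SAP reference exposure A<sub>j</sub><sup>res</sup> is the side-chain SASA
of residue X in an extended Gly-X-Gly host peptide, computed with this same
engine and frozen as packaged data.  Reference tables derived from solvated MD
ensembles are typically some tens of percent smaller; a user-supplied table
(CSV: residue, area) substitutes via `reference_sidechain_sasa(path)`.
Glycine has no side-chain atoms under the backbone rule below, so its entry
(the HA pair area) is unused by default.

## Side-chain membership

Backbone is the fixed name set {N, CA, C, O, OXT, H, H1, H2, H3, HA, HA2,
HA3, HXT}; every other atom is side chain.  Under this rule glycine has zero
side-chain atoms.  SAP sums run over side-chain atoms j only, but the outer
per-atom index covers all atoms, buried or exposed — exposure enters solely
through A<sub>j</sub>.  The self term j = i is included when i is itself a
side-chain atom (r = 0 < R).

## Solvent-excluded surface

The SES is built in two passes on a regular grid (default spacing 0.5 Å):
first a mask of valid probe-centre positions (grid points at distance
≥ vdW + probe from every atom centre), then a Euclidean distance transform
giving each point's distance to the nearest valid probe centre.  The SES is
the marching-cubes isosurface of that field at the probe radius.  Grid padding
of max(vdW) + 2·probe + 2·spacing guarantees the boundary is bulk solvent and
the mesh is closed; interior cavities appear as separate closed components and
are kept by default (they genuinely carry surface area; a
`largest_component` flag drops them).

Two numerical corrections control the O(spacing) bias of the voxelized
construction.  Near the extraction level, the transform's value is replaced by
the exact penetration depth of the deepest inflated sphere whenever the radial
projection out of that sphere is a valid probe centre — exact wherever the
surface is locally convex; re-entrant grooves keep the voxel-accurate value.
Second, one midpoint subdivision is applied to the mesh and the new vertices
are projected onto the exact isosurface under the same convexity test, which
removes most of the inscribed-polyhedron area deficit of marching cubes.  With
both, a single atom's mesh area is within 0.8% of 4πr² at the default spacing
and converges monotonically as the grid is refined.  Per-vertex areas assign
one third of each triangle's area to each of its vertices, so they conserve
the total mesh area exactly.

## Scores

Direct and positive surface scores are plain (clamped) SASA-weighted sums.
SAP uses a strict r < R cutoff with R = 5 Å by default (a 10 Å override
reproduces the common alternative); both the accelerated and brute-force paths
accumulate contributions in ascending atom order so they agree bit-for-bit.
The MLP at a mesh vertex is the g-weighted average of atomic h over atoms
within R, with g the mirrored logistic of steepness α = 1.5 Å⁻¹ and midpoint
R/2; it is therefore always bounded by the contributing atoms' min/max h.  A
weight sum below 1e-12 (possible only for a vertex far from every atom, which
cannot occur for an SES vertex under the defaults) yields MLP = 0 with a
warning.  The Heiden score sums positive vertex MLP times vertex area.

## Ensemble averaging

For frame ensembles from boosted MD, the boost energy ΔV collected while a
frame is representative is reweighted out via the second-order cumulant
expansion: log w ∝ β·mean(ΔV) + β²/2·var(ΔV) per frame (β = 1/k<sub>B</sub>T,
population variance over the frame's own sample block), normalized by
log-sum-exp.  Weights are invariant to adding a constant to all ΔV and reduce
to uniform for constant boost or absent statistics.  Statistics are per frame;
no binning over collective variables is attempted.

## Benchmarking

`pearson_benchmark` reports the Pearson correlation per (scale, method)
against an id → retention mapping, requiring at least three matched ids and
nonzero variance on both sides; unmatched ids on either side are logged, never
silently dropped.  Spearman is available behind a flag but Pearson is the
reported statistic.

## Synthetic fixtures — what they show and what they do not

All tests run on generated inputs: single atoms with closed-form SASA/SES
expectations, extended peptides built by seeded distance-geometry embedding
with backbone dihedrals set to 180° (standard atom names for all 20 residues,
which exercises the atomic typing tables end to end), and random atom clusters
for oracle-equivalence and monotonicity properties.  These establish the
correctness of the geometry engines, the assignment tables, and the score
arithmetic.  They do not establish predictive power on real antibodies: that
depends on structure quality (homology-model side-chain packing in
particular), conformational sampling, and the experimental dataset's sequence
diversity, none of which a synthetic fixture can emulate.  Cavities in real
structures contribute SES area that may be inaccessible to a chromatography
column, which is why the cavity meshes are kept separate components and can be
excluded when exploring that effect.

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| probe radius | 1.4 Å | water-sized probe for SASA and SES |
| SASA points | 960 | golden-spiral quadrature per atom |
| grid spacing | 0.5 Å | SES distance grid resolution |
| SAP cutoff R | 5 Å | neighbourhood radius (also the MLP cutoff) |
| MLP steepness α | 1.5 Å⁻¹ | logistic decay of the distance weight |
| temperature | 300 K | β in cumulant reweighting |
| radius set | Bondi | per-element van der Waals radii |

Problem sizes used in the shipped tests and the acceptance script (short
peptides, 30-atom random clusters, 0.3–0.8 Å grids) were chosen so every
closed-form or oracle comparison is sharp while the whole suite stays
interactive; all engines accept full Fv-scale structures through the same
interfaces.
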