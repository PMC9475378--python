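"""Synthetic structures with closed-form expectations.

Everything the pipeline needs can be generated here with no downloads:
single-atom "structures" whose SASA and SES areas are known analytically,
idealized extended peptides built with RDKit (used for atomic-scale typing and
the packaged reference side-chain areas), and random atom clusters for
property-based tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scales import CANONICAL_RESIDUES
from .structure import Atom, Structure, assign_radii, flag_sidechain, BONDI_RADII

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class Fixture:
    """A synthetic structure plus closed-form expectations (value, tolerance)."""

    structure: Structure
    expectations: Mapping[str, tuple[float, float]] = field(default_factory=dict)


def make_single_atom(element: str = "O", radius: float = 1.52,
                     residue: str = "GLY", probe_radius: float = 1.4,
                     center=(0.0, 0.0, 0.0), label: str = "single-atom") -> Fixture:
    """One isolated atom: SASA is the inflated sphere, SES its vdW sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    atom = Atom(index=0, name=element, element=element, res_name=residue,
                res_id=1, chain_id="A", xyz=np.asarray(center, dtype=float),
                vdw_radius=radius, is_sidechain=False)
    st = Structure([atom], label=label)
    sasa = 4.0 * np.pi * (radius + probe_radius) ** 2
    ses = 4.0 * np.pi * radius ** 2
    return Fixture(st, {"sasa": (sasa, 0.01 * sasa), "ses_area": (ses, 0.03 * ses)})


def merge_fixtures(a: Fixture, b: Fixture, separation: float = 100.0,
                   label: str = "merged") -> Fixture:
    """Place two fixtures far apart along x; additive expectations."""
    atoms = []
    for atom in a.structure.atoms:
        atoms.append(Atom(index=len(atoms), name=atom.name, element=atom.element,
                          res_name=atom.res_name, res_id=1, chain_id="A",
                          xyz=atom.xyz.copy(), vdw_radius=atom.vdw_radius,
                          is_sidechain=atom.is_sidechain))
    shift = np.array([separation, 0.0, 0.0])
    for atom in b.structure.atoms:
        atoms.append(Atom(index=len(atoms), name=atom.name, element=atom.element,
                          res_name=atom.res_name, res_id=2, chain_id="A",
                          xyz=atom.xyz + shift, vdw_radius=atom.vdw_radius,
                          is_sidechain=atom.is_sidechain))
    exp = {}
    for key in set(a.expectations) & set(b.expectations):
        (va, ta), (vb, tb) = a.expectations[key], b.expectations[key]
        exp[key] = (va + vb, ta + tb)
    return Fixture(Structure(atoms, label=label), exp)


def _hydrogen_names(mol) -> dict[int, str]:
    """Assign PDB-convention names to RDKit hydrogens by their heavy-atom parent.

    The suffix is the heavy atom's name minus its leading element letter
    (CB -> HB, CG1 -> HG1, SG -> HG); a lone hydrogen keeps the bare suffix,
    multiple hydrogens are numbered 1..n.  Backbone amide H is "H", terminal
    amine hydrogens are H1/H2/H3, the carboxylic-acid hydrogen is HXT.
    """
    names: dict[int, str] = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        info = atom.GetMonomerInfo()
        if info is None:
            continue
        heavy = info.GetName().strip()
        hs = [nb for nb in atom.GetNeighbors() if nb.GetAtomicNum() == 1]
        if not hs:
            continue
        suffix = heavy[1:]
        if heavy == "N":
            hnames = ["H"] if len(hs) == 1 else [f"H{k + 1}" for k in range(len(hs))]
        elif heavy == "OXT":
            hnames = ["HXT"]
        elif heavy == "CA" and len(hs) == 2:
            hnames = ["HA2", "HA3"]  # glycine convention
        elif len(hs) == 1:
            hnames = [f"H{suffix}"]
        else:
            hnames = [f"H{suffix}{k + 1}" for k in range(len(hs))]
        for hatom, hname in zip(hs, hnames):
            names[hatom.GetIdx()] = hname
    return names


def mol_to_structure(mol, label: str = "peptide") -> Structure:
    """Convert an RDKit molecule with PDB residue info and a conformer."""
    from .scales import canonicalize_residue

    conf = mol.GetConformer()
    hnames = _hydrogen_names(mol)
    atoms = []
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        if atom.GetAtomicNum() == 1:
            parent = atom.GetNeighbors()[0]
            info = parent.GetMonomerInfo()
            name = hnames.get(idx, "H")
        else:
            info = atom.GetMonomerInfo()
            name = info.GetName().strip()
        pos = conf.GetAtomPosition(idx)
        orig = info.GetResidueName().strip()
        atoms.append(Atom(index=len(atoms), name=name,
                          element=atom.GetSymbol().upper(),
                          res_name=canonicalize_residue(orig),
                          res_id=info.GetResidueNumber(),
                          chain_id=(info.GetChainId() or "A").strip() or "A",
                          xyz=np.array([pos.x, pos.y, pos.z]),
                          orig_res_name=orig))
    order = sorted(range(len(atoms)), key=lambda i: (atoms[i].chain_id, atoms[i].res_id))
    atoms = [atoms[i] for i in order]
    for i, a in enumerate(atoms):
        a.index = i
    return Structure(atoms, label=label)


def build_peptide_mol(sequence: str, seed: int = 2025):
    """RDKit molecule for an extended peptide (hydrogens added and named).

    The 3D conformation is produced by a seeded distance-geometry embedding,
    after which the backbone dihedrals (phi, psi, omega) are set to 180 deg for
    a reproducible extended conformation.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem, rdMolTransforms

    sequence = sequence.strip().upper()
    if not sequence:
        raise ValueError("sequence must contain at least one residue")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise ValueError(f"unknown residue code(s) {bad}; use one-letter codes "
                         f"for the 20 canonical amino acids")
    mol = Chem.MolFromSequence(sequence)
    if mol is None:
        raise ValueError(f"could not build peptide for sequence {sequence!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(mol, params) != 0:
        # long flexible chains occasionally fail distance-geometry smoothing;
        # random-coordinate initialization is the standard fallback
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise RuntimeError(f"3D embedding failed for sequence {sequence!r}")
    # straighten the backbone: phi = psi = omega = 180 degrees
    conf = mol.GetConformer()
    by_res: dict[int, dict[str, int]] = {}
    for atom in mol.GetAtoms():
        info = atom.GetMonomerInfo()
        if atom.GetAtomicNum() != 1 and info is not None:
            name = info.GetName().strip()
            if name in ("N", "CA", "C"):
                by_res.setdefault(info.GetResidueNumber(), {})[name] = atom.GetIdx()
    resnums = sorted(by_res)
    for prev, cur in zip(resnums, resnums[1:]):
        p, c = by_res[prev], by_res[cur]
        try:
            rdMolTransforms.SetDihedralDeg(conf, p["CA"], p["C"], c["N"], c["CA"], 180.0)
            rdMolTransforms.SetDihedralDeg(conf, p["C"], c["N"], c["CA"], c["C"], 180.0)
        except Exception:
            pass  # proline omega/phi may be constrained by the ring
    for prev, cur in zip(resnums, resnums[1:]):
        p, c = by_res[prev], by_res[cur]
        try:
            rdMolTransforms.SetDihedralDeg(conf, p["N"], p["CA"], p["C"], c["N"], 180.0)
        except Exception:
            pass
    return mol


def make_ideal_peptide(sequence: str, seed: int = 2025,
                       assign: bool = True) -> Fixture:
    """Extended peptide with standard atom names, radii and side-chain flags set."""
    mol = build_peptide_mol(sequence, seed=seed)
    st = mol_to_structure(mol, label=f"peptide-{sequence}")
    if assign:
        assign_radii(st)
        flag_sidechain(st)
    return Fixture(st, {})


def make_random_cluster(n_atoms: int, rng: np.random.Generator | int = 0,
                        box: float = 12.0, label: str = "random-cluster") -> Fixture:
    """Random atoms in a box with random residue labels, radii, side-chain flags.

    Coordinates are re-drawn until no two atoms coincide, so SASA and SAP are
    well defined.  Used by oracle-equivalence and monotonicity property tests.
    """
    rng = np.random.default_rng(rng)
    elements = np.array(["C", "N", "O", "S", "H"])
    atoms = []
    coords = rng.uniform(0, box, size=(n_atoms, 3))
    while len(coords) > 1 and (np.linalg.norm(
            coords[:, None] - coords[None, :], axis=2)[np.triu_indices(n_atoms, 1)] < 0.2).any():
        coords = rng.uniform(0, box, size=(n_atoms, 3))
    for i in range(n_atoms):
        el = str(rng.choice(elements))
        res = str(rng.choice(CANONICAL_RESIDUES))
        atoms.append(Atom(index=i, name=f"{el}{i}", element=el, res_name=res,
                          res_id=i + 1, chain_id="A", xyz=coords[i],
                          vdw_radius=BONDI_RADII[el],
                          is_sidechain=bool(rng.integers(0, 2))))
    return Fixture(Structure(atoms, label=label), {})


#: A tiny hand-written PDB (one alanine) to exercise the parser without files.
MINI_PDB = """\
ATOM      1  N   ALA A   1      -0.525   1.362   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       1.520   0.000   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       2.197   0.000   1.025  1.00  0.00           O
ATOM      5  CB  ALA A   1      -0.507  -0.785  -1.207  1.00  0.00           C
ATOM      6  H   ALA A   1      -1.125   1.529   0.797  1.00  0.00           H
ATOM      7  HA  ALA A   1      -0.322  -0.497   0.923  1.00  0.00           H
ATOM      8  HB1 ALA A   1      -0.163  -1.820  -1.164  1.00  0.00           H
ATOM      9  HB2 ALA A   1      -1.598  -0.781  -1.216  1.00  0.00           H
ATOM     10  HB3 ALA A   1      -0.144  -0.311  -2.121  1.00  0.00           H
TER
END
"""
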