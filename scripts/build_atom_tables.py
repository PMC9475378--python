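"""Regenerate the packaged atomic tables.

Writes, under src/hydroscore/data/:

* crippen_atoms.csv       — Wildman-Crippen logP atom contributions per
                            (residue, atom name), typed with RDKit on
                            Gly-X-Gly host peptides (mid-chain context) plus
                            single-residue molecules for terminal atoms, with
                            the aromatic-N hydrogen override for TRP/HIS;
* eisenberg_dg_atoms.csv  — Eisenberg-McLachlan atomic solvation parameters
                            (kcal/mol/A^2) keyed the same way;
* ref_sidechain_sasa.csv  — side-chain SASA of each residue in an extended
                            Gly-X-Gly host (probe 1.4 A, 960 points), the SAP
                            reference denominator.

Deterministic: fixed embedding seed, fixed quadrature.  Run from the repo root:
    python scripts/build_atom_tables.py
"""

from __future__ import annotations

import csv
import os
import sys
from collections import defaultdict

from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit import RDConfig

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from hydroscore.fixtures import ONE_TO_THREE, _hydrogen_names, make_ideal_peptide
from hydroscore.sasa import shrake_rupley

DATA_DIR = os.path.join(os.path.dirname(__file__), "..", "src", "hydroscore", "data")
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

CRIPPEN_PROV = "Wildman & Crippen 1999 logP contributions via RDKit; TRP/HIS aromatic N-H set to amine type H3"
EDG_PROV = "Eisenberg & McLachlan 1986 atomic solvation parameters (kcal/mol/A^2); united-atom, hydrogens 0"

H3_AMINE_VALUE = 0.2142  # Wildman-Crippen H3 ("amine" hydrogen) logP contribution


def crippen_label_map():
    """label -> logP value from RDKit's parameter file (to recover type labels)."""
    path = os.path.join(RDConfig.RDDataDir, "Crippen.txt")
    out = {}
    for line in open(path):
        if line.startswith("#") or not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) >= 3 and parts[2].strip():
            out.setdefault(round(float(parts[2]), 4), parts[0].strip())
    return out


def typed_contribs(mol):
    """(atom idx) -> (label, logP contribution), with the TRP/HIS N-H override."""
    value_to_label = crippen_label_map()
    contribs = rdMolDescriptors._CalcCrippenContribs(mol)
    out = {}
    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        logp = contribs[idx][0]
        label = value_to_label.get(round(logp, 4), "?")
        if atom.GetAtomicNum() == 1:
            nb = atom.GetNeighbors()[0]
            res = _resname(nb)
            if nb.GetSymbol() == "N" and nb.GetIsAromatic() and res in ("TRP", "HIS", "HID", "HIE", "HIP"):
                label, logp = "H3", H3_AMINE_VALUE
        out[idx] = (label, logp)
    return out


def _resname(atom):
    info = atom.GetMonomerInfo()
    return info.GetResidueName().strip() if info else ""


def atom_names(mol):
    """idx -> PDB atom name (hydrogens named by the shared convention)."""
    hnames = _hydrogen_names(mol)
    names = {}
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            names[atom.GetIdx()] = hnames.get(atom.GetIdx(), "H")
        else:
            names[atom.GetIdx()] = atom.GetMonomerInfo().GetName().strip()
    return names


def residue_of(mol):
    """idx -> (residue name, residue number); hydrogens follow their heavy atom."""
    out = {}
    for atom in mol.GetAtoms():
        a = atom.GetNeighbors()[0] if atom.GetAtomicNum() == 1 else atom
        info = a.GetMonomerInfo()
        out[atom.GetIdx()] = (info.GetResidueName().strip(), info.GetResidueNumber())
    return out


def host_mol(letter):
    """G-X-G tripeptide with hydrogens (no 3D needed for typing)."""
    mol = Chem.MolFromSequence(f"G{letter}G")
    return Chem.AddHs(mol)


def single_mol(letter):
    mol = Chem.MolFromSequence(letter)
    return Chem.AddHs(mol)


def his_variant(protonation):
    """Capped HIS tautomers: HID (H on ND1), HIE (H on NE2), HIP (both, +1)."""
    mol = Chem.MolFromSequence("GHG")
    rw = Chem.RWMol(mol)
    nd1 = ne2 = None
    for atom in rw.GetAtoms():
        info = atom.GetMonomerInfo()
        if info and info.GetResidueName().strip() == "HIS":
            name = info.GetName().strip()
            if name == "ND1":
                nd1 = atom
            elif name == "NE2":
                ne2 = atom
    assert nd1 is not None and ne2 is not None
    for atom in (nd1, ne2):
        atom.SetNoImplicit(True)
        atom.SetNumExplicitHs(0)
        atom.SetFormalCharge(0)
    if protonation == "HID":
        nd1.SetNumExplicitHs(1)
    elif protonation == "HIE":
        ne2.SetNumExplicitHs(1)
    elif protonation == "HIP":
        nd1.SetNumExplicitHs(1)
        ne2.SetNumExplicitHs(1)
        ne2.SetFormalCharge(1)
    else:
        raise ValueError(protonation)
    Chem.SanitizeMol(rw)
    return Chem.AddHs(rw)


def collect(mol, target_resnum, rename=None):
    names = atom_names(mol)
    resof = residue_of(mol)
    typed = typed_contribs(mol)
    entries = {}
    for idx, (label, logp) in typed.items():
        res, num = resof[idx]
        if num != target_resnum:
            continue
        res = rename or res
        entries[(res, names[idx])] = (label, logp)
    return entries


def build_crippen():
    entries = {}
    for letter, res in sorted(ONE_TO_THREE.items(), key=lambda kv: kv[1]):
        entries.update(collect(host_mol(letter), 2))
        # terminal-only atoms from the free amino acid (H1/H2/H3, OXT, HXT)
        term = collect(single_mol(letter), 1)
        for key, val in term.items():
            if key not in entries:
                entries[key] = val
        if (res, "H1") in entries and (res, "H3") not in entries:
            entries[(res, "H3")] = entries[(res, "H1")]  # protonated N-terminus
    # histidine protonation variants, plus a merged HIS covering all their atoms
    his_union = {}
    for prot in ("HID", "HIE", "HIP"):
        var = collect(his_variant(prot), 2, rename=prot)
        entries.update(var)
        for (res, atom), val in var.items():
            his_union.setdefault(("HIS", atom), val)
    # variant-specific atoms (HD1/HE2) folded into the canonical HIS entry set
    for key, val in his_union.items():
        entries.setdefault(key, val)
    return entries


def build_eisenberg_dg(keys):
    """Assign Eisenberg-McLachlan solvation classes by residue + atom name."""
    charged_o = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
    charged_n = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                 ("HIP", "ND1"), ("HIP", "NE2")}
    entries = {}
    for res, atom in keys:
        el = atom[0]
        if el == "H":
            entries[(res, atom)] = ("H", 0.0)
        elif el == "C":
            entries[(res, atom)] = ("C", 0.016)
        elif el == "S":
            entries[(res, atom)] = ("S", 0.021)
        elif el == "O":
            if (res, atom) in charged_o or atom == "OXT":
                entries[(res, atom)] = ("O-", -0.024)
            else:
                entries[(res, atom)] = ("O/N", -0.006)
        elif el == "N":
            if (res, atom) in charged_n:
                entries[(res, atom)] = ("N+", -0.050)
            else:
                entries[(res, atom)] = ("O/N", -0.006)
        else:
            raise ValueError(f"unexpected element for {(res, atom)}")
    return entries


def write_table(path, entries, provenance):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "atom", "type", "value", "provenance"])
        for (res, atom), (label, val) in sorted(entries.items()):
            w.writerow([res, atom, label, f"{val:.4f}", provenance])


def build_reference_sasa():
    rows = []
    for letter, res in sorted(ONE_TO_THREE.items(), key=lambda kv: kv[1]):
        fx = make_ideal_peptide(f"G{letter}G", seed=2025)
        st = fx.structure
        sasa = shrake_rupley(st, probe_radius=1.4, n_points=960)
        if res == "GLY":
            # no side-chain atoms under the backbone rule; store the HA pair
            # area for completeness (unused by default)
            area = sum(sasa.atom_area[a.index] for a in st.atoms
                       if a.res_id == 2 and a.name in ("HA2", "HA3"))
            note = "unused by default (GLY has no side-chain atoms)"
        else:
            area = sum(sasa.atom_area[a.index] for a in st.atoms
                       if a.res_id == 2 and a.is_sidechain)
            note = "extended GXG host, probe 1.4 A, 960 points"
        rows.append((res, area, note))
    return rows


def main():
    os.makedirs(DATA_DIR, exist_ok=True)
    crippen = build_crippen()
    write_table(os.path.join(DATA_DIR, "crippen_atoms.csv"), crippen, CRIPPEN_PROV)
    print(f"crippen_atoms.csv: {len(crippen)} entries")
    edg = build_eisenberg_dg(crippen.keys())
    write_table(os.path.join(DATA_DIR, "eisenberg_dg_atoms.csv"), edg, EDG_PROV)
    print(f"eisenberg_dg_atoms.csv: {len(edg)} entries")
    ref = build_reference_sasa()
    with open(os.path.join(DATA_DIR, "ref_sidechain_sasa.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue", "area", "provenance"])
        for res, area, note in ref:
            w.writerow([res, f"{area:.3f}", note])
    print("ref_sidechain_sasa.csv:", len(ref), "entries")


if __name__ == "__main__":
    main()
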