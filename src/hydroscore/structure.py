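"""Atom/structure data model, PDB I/O, van der Waals radii, side-chain flags.

The structure model is deliberately small: an ordered list of atoms with names,
residue labels, chain ids, Cartesian coordinates in Angstrom, and per-atom van
der Waals radii.  Reading goes through Biopython's PDB parser; residue-name
dialects produced by modelling packages (HID/HIE/HIP, CYX, MSE) are
canonicalized for scoring while the original names are retained for provenance
and for protonation-aware atomic scales.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .scales import canonicalize_residue

# Bondi (1964) van der Waals radii, Angstrom.  Covers the elements found in
# proteins and common ligands; extend via the `extra` argument of assign_radii.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90, "ZN": 1.39,
}

RADIUS_SETS = {"bondi": BONDI_RADII}

#: Atom names treated as backbone; everything else is side chain.
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HXT"}
)


@dataclass
class Atom:
    index: int
    name: str
    element: str
    res_name: str            # canonical residue key used for scoring
    res_id: int
    chain_id: str
    xyz: np.ndarray          # shape (3,), Angstrom
    vdw_radius: float | None = None
    is_sidechain: bool | None = None
    icode: str = ""
    orig_res_name: str = ""  # name as read from the file (HIE, CYX, ...)

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name!r}: vdw_radius must be positive")
        if not self.orig_res_name:
            self.orig_res_name = self.res_name


@dataclass
class Structure:
    """An ordered collection of atoms grouped into residues."""

    atoms: list[Atom]
    label: str = "structure"

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a Structure must contain at least one atom")

    def __len__(self):
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        r = [a.vdw_radius for a in self.atoms]
        if any(v is None for v in r):
            raise ValueError("van der Waals radii not assigned; call assign_radii first")
        return np.array(r, dtype=float)

    @property
    def sidechain_mask(self) -> np.ndarray:
        m = [a.is_sidechain for a in self.atoms]
        if any(v is None for v in m):
            raise ValueError("side-chain flags not set; call flag_sidechain first")
        return np.array(m, dtype=bool)

    def residues(self) -> list[tuple[tuple[str, int, str], list[Atom]]]:
        """Group atoms by (chain, residue id, insertion code), preserving order."""
        groups: dict = {}
        for a in self.atoms:
            groups.setdefault((a.chain_id, a.res_id, a.icode), []).append(a)
        for key, atoms in groups.items():
            names = {a.res_name for a in atoms}
            if len(names) != 1:
                raise ValueError(f"residue {key} has inconsistent residue names {names}")
        return list(groups.items())

    def chains(self) -> list[str]:
        seen = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Structure":
        """Return a rigid-body transformed copy (rotation then translation)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [replace(a, xyz=R @ a.xyz + t) for a in self.atoms]
        return Structure(atoms, label=self.label)


def read_pdb(path, chains: Sequence[str] | None = None, model: int = 0,
             include_hetero: bool = False, label: str | None = None) -> Structure:
    """Read a PDB file into a Structure.

    Waters and hetero records are excluded by default; for disordered atoms the
    highest-occupancy alternate location is kept; residue names are
    canonicalized (original kept in ``orig_res_name``).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(label or path.stem, str(path))
    except Exception as exc:
        raise ValueError(f"failed to parse PDB file {path}: {exc}") from exc
    models = list(bio)
    if not models:
        raise ValueError(f"{path}: no models found")
    if model >= len(models):
        raise ValueError(f"{path}: model {model} requested but file has {len(models)}")
    mdl = models[model]
    available = [c.id for c in mdl]
    if chains is not None:
        missing = [c for c in chains if c not in available]
        if missing:
            raise ValueError(f"{path}: chain(s) {missing} not found; available: {available}")
    atoms: list[Atom] = []
    for chain in mdl:
        if chains is not None and chain.id not in chains:
            continue
        for residue in chain:
            hetflag, resseq, icode = residue.id
            if hetflag != " " and not include_hetero:
                continue
            orig = residue.get_resname().strip()
            canon = canonicalize_residue(orig)
            for batom in residue:
                if batom.is_disordered():
                    batom = max(batom, key=lambda a: a.get_occupancy() or 0.0)
                element = (batom.element or _guess_element(batom.get_name())).strip().upper()
                atoms.append(Atom(
                    index=len(atoms), name=batom.get_name().strip(), element=element,
                    res_name=canon, res_id=resseq, chain_id=chain.id,
                    xyz=np.array(batom.get_coord(), dtype=float),
                    icode=icode.strip(), orig_res_name=orig,
                ))
    if not atoms:
        raise ValueError(f"{path}: no atoms left after filtering "
                         f"(chains={chains}, include_hetero={include_hetero})")
    return Structure(atoms, label=label or path.stem)


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip().upper().lstrip("0123456789")
    if name[:2] in ("CL", "BR", "SE", "ZN", "MG", "FE", "NA"):
        return name[:2]
    return name[:1]


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM records (fixed-width PDB format, 3 decimals on coordinates)."""
    with open(path, "w") as fh:
        last_chain = None
        for a in structure.atoms:
            if last_chain is not None and a.chain_id != last_chain:
                fh.write("TER\n")
            last_chain = a.chain_id
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.index + 1:5d} {name:<4s} {a.res_name:<3s} {a.chain_id:1s}"
                f"{a.res_id:4d}{a.icode or ' ':1s}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
            )
        fh.write("TER\nEND\n")


def assign_radii(structure: Structure, radius_set: str = "bondi",
                 extra: dict | None = None) -> Structure:
    """Fill per-atom van der Waals radii by element (in place; returns structure)."""
    try:
        table = dict(RADIUS_SETS[radius_set])
    except KeyError:
        raise KeyError(f"unknown radius set {radius_set!r}; available: {list(RADIUS_SETS)}")
    if extra:
        table.update({k.upper(): float(v) for k, v in extra.items()})
    for a in structure.atoms:
        el = a.element.upper()
        if el not in table:
            raise KeyError(f"element {a.element!r} (atom {a.name}) not in radius set "
                           f"{radius_set!r}")
        a.vdw_radius = table[el]
    return structure


def flag_sidechain(structure: Structure) -> Structure:
    """Set is_sidechain: false for backbone atom names, true otherwise (in place)."""
    for a in structure.atoms:
        a.is_sidechain = a.name.strip().upper() not in BACKBONE_ATOMS
    return structure


def strip_hydrogens(structure: Structure) -> Structure:
    """Return a copy without hydrogen atoms (for sensitivity checks)."""
    atoms = [replace(a, index=i) for i, a in
             enumerate(a for a in structure.atoms if a.element.upper() != "H")]
    if not atoms:
        raise ValueError("structure contains only hydrogens")
    return Structure(atoms, label=structure.label)
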