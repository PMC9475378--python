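"""Hydrophobicity scales: registry, normalization, and per-atom assignment.

Residue scales map three-letter residue codes to dimensionless hydrophobicity
values h; atomic scales map (residue name, atom name) pairs.  The nine packaged
residue scales are stored pre-normalized: Gly is shifted to zero and the values
are divided by the population standard deviation, so hydrophobic residues are
positive and the variance of each scale is one.  The two packaged atomic scales
(Wildman-Crippen logP contributions and Eisenberg-McLachlan atomic solvation
parameters) are kept on their native physical units.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

CANONICAL_RESIDUES = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

#: Variant residue names accepted on input and folded to canonical keys.
RESIDUE_SYNONYMS = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS", "CYX": "CYS", "CYM": "CYS", "MSE": "MET",
    "ASH": "ASP", "GLH": "GLU", "LYN": "LYS",
}

#: Alternate hydrogen / terminal-atom nomenclatures folded to the packaged names.
ATOM_NAME_SYNONYMS = {
    "HN": "H", "1H": "H1", "2H": "H2", "3H": "H3",
    "HT1": "H1", "HT2": "H2", "HT3": "H3", "OT1": "O", "OT2": "OXT",
    "O1": "O", "O2": "OXT", "OXT1": "OXT",
}

RESIDUE_SCALES = (
    "bandyopadhyay-mehler", "black-mould", "eisenberg", "kyte-doolittle",
    "meek", "rose", "wimley-white", "jain", "miyazawa",
)
ATOMIC_SCALES = ("crippen", "eisenberg-dg")


def canonicalize_residue(name: str) -> str:
    """Map a residue-name dialect (HID/HIE/HIP, CYX, MSE, ...) to its canonical key."""
    name = name.strip().upper()
    return RESIDUE_SYNONYMS.get(name, name)


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named hydrophobicity scale.

    ``values`` is keyed by residue name for residue scales and by
    ``(residue name, atom name)`` for atomic scales.
    """

    name: str
    resolution: str            # "residue" | "atomic"
    values: Mapping
    normalized: bool
    provenance: str = ""

    def __post_init__(self):
        if self.resolution not in ("residue", "atomic"):
            raise ValueError(f"resolution must be 'residue' or 'atomic', got {self.resolution!r}")
        for v in self.values.values():
            if not math.isfinite(v):
                raise ValueError(f"scale {self.name!r} contains a non-finite value")
        if self.resolution == "residue":
            keys = set(self.values)
            missing = set(CANONICAL_RESIDUES) - keys
            if missing:
                raise ValueError(f"scale {self.name!r} is missing residues: {sorted(missing)}")
        if self.normalized and self.resolution == "residue":
            vals = np.array([self.values[r] for r in CANONICAL_RESIDUES])
            if abs(self.values["GLY"]) > 0.005:
                raise ValueError(f"normalized scale {self.name!r} has GLY != 0")
            if abs(np.var(vals) - 1.0) > 0.02:
                raise ValueError(f"normalized scale {self.name!r} has variance != 1")

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"HydrophobicityScale(name={self.name!r}, resolution={self.resolution!r}, "
                f"n_values={len(self.values)}, normalized={self.normalized})")


@dataclass(frozen=True)
class AtomTypeTable:
    """Per-atom typing table: (residue name, atom name) -> (type label, h value)."""

    name: str
    entries: Mapping
    provenance: str = ""

    def to_scale(self, normalized: bool = False) -> HydrophobicityScale:
        values = {key: hv for key, (_, hv) in self.entries.items()}
        return HydrophobicityScale(self.name, "atomic", values, normalized, self.provenance)


def available_scales() -> list[str]:
    """Names of all registered scales (nine residue-level, two atomic)."""
    return list(RESIDUE_SCALES) + list(ATOMIC_SCALES)


def _read_residue_scale_file(name: str) -> HydrophobicityScale:
    text = (resources.files("hydroscore.data") / "scales" / f"{name}.txt").read_text()
    meta, values = {}, {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta[key.strip()] = val.strip()
        else:
            res, val = line.split()
            values[res] = float(val)
    return HydrophobicityScale(
        name=meta.get("name", name),
        resolution=meta.get("resolution", "residue"),
        values=values,
        normalized=meta.get("normalized", "false").lower() == "true",
        provenance=meta.get("provenance", ""),
    )


def load_atom_table(name: str) -> AtomTypeTable:
    """Load a packaged atomic typing table ('crippen' or 'eisenberg-dg')."""
    fname = {"crippen": "crippen_atoms.csv", "eisenberg-dg": "eisenberg_dg_atoms.csv"}.get(name)
    if fname is None:
        raise KeyError(f"unknown atomic table {name!r}; available: {list(ATOMIC_SCALES)}")
    text = (resources.files("hydroscore.data") / fname).read_text()
    entries = {}
    provenance = ""
    reader = csv.DictReader(line for line in text.splitlines() if not line.startswith("#"))
    for row in reader:
        entries[(row["residue"], row["atom"])] = (row["type"], float(row["value"]))
        provenance = row.get("provenance", provenance) or provenance
    return AtomTypeTable(name=name, entries=entries, provenance=provenance)


def load_scale(name: str) -> HydrophobicityScale:
    """Load a registered scale by name.

    Raises ``KeyError`` listing the registered names when ``name`` is unknown.
    """
    key = name.strip().lower()
    if key in RESIDUE_SCALES:
        return _read_residue_scale_file(key)
    if key in ATOMIC_SCALES:
        return load_atom_table(key).to_scale()
    raise KeyError(f"unknown scale {name!r}; registered scales: {available_scales()}")


def normalize_scale(raw: Mapping[str, float], name: str = "custom",
                    provenance: str = "") -> HydrophobicityScale:
    """Normalize a raw residue scale to the packaged convention.

    The values are shifted so Gly is exactly zero, divided by the population
    standard deviation (variance of the 20 values becomes one), and the sign is
    flipped if needed so hydrophobic residues come out positive (operationalized
    as: the mean over Ile/Leu/Phe/Val must be non-negative).
    """
    raw = {canonicalize_residue(k): float(v) for k, v in raw.items()}
    missing = [r for r in CANONICAL_RESIDUES if r not in raw]
    if missing:
        raise ValueError(f"raw scale is missing residues: {missing}")
    x = np.array([raw[r] for r in CANONICAL_RESIDUES], dtype=float)
    sd = float(np.std(x))
    if sd < 1e-12:
        raise ValueError("raw scale has zero spread; cannot normalize")
    h = (x - raw["GLY"]) / sd
    values = dict(zip(CANONICAL_RESIDUES, h))
    if np.mean([values[r] for r in ("ILE", "LEU", "PHE", "VAL")]) < 0:
        values = {k: -v for k, v in values.items()}
    return HydrophobicityScale(name, "residue", values, normalized=True,
                               provenance=provenance or "normalized user scale")


def assign_hydrophobicity(structure, scale: HydrophobicityScale,
                          on_unknown: str = "error") -> np.ndarray:
    """Assign a hydrophobicity value to every atom of ``structure``.

    Residue scales assign each atom its residue's value; all histidine
    protonation variants receive the HIS value unless the scale carries an
    explicit per-variant entry.  Atomic scales look atoms up by
    (residue, atom name), resolving common name synonyms.

    ``on_unknown`` controls non-canonical residues (ligands, waters):
    ``"error"`` raises, ``"skip"`` assigns h=0 with a warning.
    """
    import warnings

    if on_unknown not in ("error", "skip"):
        raise ValueError("on_unknown must be 'error' or 'skip'")
    out = np.zeros(len(structure.atoms), dtype=float)
    for i, atom in enumerate(structure.atoms):
        raw_name = atom.res_name.strip().upper()
        canon = canonicalize_residue(raw_name)
        if scale.resolution == "residue":
            if raw_name in scale.values:       # per-protonation entry, if shipped
                out[i] = scale.values[raw_name]
            elif canon in scale.values:
                out[i] = scale.values[canon]
            elif on_unknown == "skip":
                warnings.warn(f"residue {raw_name!r} not in scale {scale.name!r}; h=0")
            else:
                raise KeyError(f"residue {raw_name!r} (canonical {canon!r}) not in "
                               f"scale {scale.name!r}")
        else:
            aname = atom.name.strip().upper()
            candidates = [(raw_name, aname), (canon, aname)]
            syn = ATOM_NAME_SYNONYMS.get(aname)
            if syn is not None:
                candidates += [(raw_name, syn), (canon, syn)]
            for key in candidates:
                if key in scale.values:
                    out[i] = scale.values[key]
                    break
            else:
                if canon not in CANONICAL_RESIDUES and on_unknown == "skip":
                    warnings.warn(f"residue {raw_name!r} not typed by {scale.name!r}; h=0")
                else:
                    raise KeyError(f"atom ({raw_name}, {aname}) has no entry in atomic "
                                   f"scale {scale.name!r}")
    return out
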