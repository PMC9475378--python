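"""Per-atom solvent-accessible surface area (Shrake-Rupley quadrature).

Each atom is inflated by the probe radius (1.4 A by default, a water-sized
probe) and covered with a deterministic golden-spiral point set; the accessible
fraction of points — those not inside any other inflated sphere — times the
inflated-sphere area gives the atom's SASA.  The quadrature sphere is fixed for
a given point count, so results are exactly reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one quadrature point")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass(frozen=True)
class SasaResult:
    """Per-atom solvent-accessible areas (A^2), aligned with the structure's atoms."""

    atom_area: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.atom_area.sum())

    def per_residue(self, structure: Structure) -> dict:
        out: dict = {}
        for (key, atoms) in structure.residues():
            out[key] = float(sum(self.atom_area[a.index] for a in atoms))
        return out


def shrake_rupley(structure: Structure, probe_radius: float = 1.4,
                  n_points: int = 960, all_pairs: bool = False) -> SasaResult:
    """Compute per-atom SASA.

    ``all_pairs=True`` bypasses the KD-tree neighbour search and tests every
    atom pair; it must (and does) give identical results and exists as the
    reference path for testing the acceleration.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a meaningful quadrature")
    if probe_radius < 0:
        raise ValueError("probe_radius must be non-negative")
    coords = structure.coords
    radii = structure.radii
    n = len(coords)
    # degenerate input guard: coincident centres make occlusion ill-defined
    tree = cKDTree(coords)
    dup = tree.query_pairs(1e-6)
    if dup:
        i, j = next(iter(dup))
        raise ValueError(f"atoms {i} and {j} have (near-)identical coordinates")
    unit = sphere_points(n_points)
    inflated = radii + probe_radius
    if all_pairs:
        neighbor_lists = [[j for j in range(n) if j != i] for i in range(n)]
    else:
        cutoff = 2.0 * inflated.max()
        neighbor_lists = tree.query_ball_tree(tree, cutoff)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= inflated[i] + inflated[j]:
                continue
            close = np.linalg.norm(pts - coords[j], axis=1) < inflated[j]
            accessible &= ~close
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * accessible.mean()
    return SasaResult(atom_area=areas, probe_radius=probe_radius, n_points=n_points)


def reference_sidechain_sasa(path=None) -> Mapping[str, float]:
    """Reference side-chain SASA per residue (A^2), the SAP denominator.

    Returns the packaged table by default: side-chain areas of each residue X
    measured in an extended Gly-X-Gly host peptide with this module's engine
    (probe 1.4 A, 960 points).  Pass ``path`` to a two-column CSV
    (residue, area) to substitute your own, e.g. MD-ensemble averages; the file
    must cover all 20 canonical residues.
    """
    if path is None:
        text = (resources.files("hydroscore.data") / "ref_sidechain_sasa.csv").read_text()
        rows = list(csv.DictReader(l for l in text.splitlines() if not l.startswith("#")))
    else:
        with open(path) as fh:
            rows = list(csv.DictReader(l for l in fh if not l.startswith("#")))
    table = {r["residue"].strip().upper(): float(r["area"]) for r in rows}
    from .scales import CANONICAL_RESIDUES
    missing = [r for r in CANONICAL_RESIDUES if r not in table]
    if missing:
        raise ValueError(f"reference side-chain SASA table is missing residues: {missing}")
    bad = [r for r, a in table.items() if a <= 0]
    if bad:
        raise ValueError(f"reference side-chain SASA must be positive; bad entries: {bad}")
    return table
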