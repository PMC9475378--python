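"""Surface-hydrophobicity scores and the HIC benchmarking harness.

Four scores are implemented, all driven by per-atom hydrophobicity values h
assigned from a scale:

* direct surface score      S_surf = sum_i h_i * A_i   over all atoms,
* positive surface score    S_pos  = sum_i max(h_i, 0) * A_i,
* spatial aggregation propensity (SAP): per atom i,
      SAP_i = sum over side-chain atoms j with r_ij < R of (A_j / A_j^res) h_j,
  scored as S_SAP = sum_i max(SAP_i, 0) over all atoms (buried ones included;
  exposure enters only through the SASA ratio),
* Heiden surface-projection score: the molecular lipophilicity potential at
  each SES mesh vertex k is the logistic-weighted average
      MLP_k = sum_j g(r_jk) h_j / sum_j g(r_jk),  g(r) = 1/(exp(alpha(r-R/2))+1)
  over atoms within the cutoff, scored as S = sum_k max(MLP_k, 0) A_k.

Defaults R = 5 A and alpha = 1.5 1/A follow the original SAP and Heiden
parameterizations.  Frame ensembles from boosted molecular dynamics are
averaged with second-order cumulant reweighting of the boost energy.
Benchmarking correlates scores against experimental hydrophobic-interaction-
chromatography (HIC) retention with the Pearson coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import logsumexp
from scipy.stats import pearsonr, spearmanr

from .ses import SurfaceMesh
from .sasa import SasaResult
from .structure import Structure

logger = logging.getLogger(__name__)

BOLTZMANN_KCAL = 0.001987204259  # kcal / (mol K)


@dataclass(frozen=True)
class ScoringParams:
    """Cutoff and weighting parameters shared by SAP and the MLP projection."""

    cutoff: float = 5.0        # R, Angstrom
    alpha: float = 1.5         # logistic steepness, 1/Angstrom
    probe_radius: float = 1.4  # Angstrom

    def __post_init__(self):
        if self.cutoff <= 0 or self.alpha <= 0:
            raise ValueError("cutoff and alpha must be positive")

    def g(self, r):
        """Logistic distance weight: 1 at contact, 1/2 at R/2, ~0 at the cutoff."""
        return 1.0 / (np.exp(self.alpha * (np.asarray(r, dtype=float) - self.cutoff / 2.0)) + 1.0)


def _check_aligned(structure: Structure, h: np.ndarray, sasa: SasaResult | None = None):
    h = np.asarray(h, dtype=float)
    if len(h) != len(structure.atoms):
        raise ValueError(f"h has {len(h)} values for {len(structure.atoms)} atoms")
    if sasa is not None and len(sasa.atom_area) != len(structure.atoms):
        raise ValueError("SASA result not aligned with structure")
    return h


def surf_score(structure: Structure, sasa: SasaResult, h: np.ndarray) -> float:
    """Direct surface score: SASA-weighted sum of per-atom hydrophobicity."""
    h = _check_aligned(structure, h, sasa)
    return float(np.dot(h, sasa.atom_area))


def pos_surf_score(structure: Structure, sasa: SasaResult, h: np.ndarray) -> float:
    """Positive surface score: hydrophilic (negative h) atoms contribute zero."""
    h = _check_aligned(structure, h, sasa)
    return float(np.dot(np.maximum(h, 0.0), sasa.atom_area))


def sap_per_atom(structure: Structure, sasa: SasaResult, h: np.ndarray,
                 reference_areas: Mapping[str, float],
                 params: ScoringParams = ScoringParams(),
                 brute_force: bool = False) -> np.ndarray:
    """Per-atom spatial aggregation propensity.

    Every atom i (side chain or backbone, exposed or buried) collects
    (A_j / A_j^residue) * h_j from the side-chain atoms j with r_ij strictly
    below the cutoff; the self term j = i is included when i is itself a
    side-chain atom.  ``brute_force=True`` evaluates all atom pairs and is the
    reference path for the KD-tree acceleration.
    """
    h = _check_aligned(structure, h, sasa)
    coords = structure.coords
    side = structure.sidechain_mask
    n = len(coords)
    ref = np.empty(n)
    for i, atom in enumerate(structure.atoms):
        if side[i]:
            try:
                ref[i] = reference_areas[atom.res_name]
            except KeyError:
                raise KeyError(f"no reference side-chain SASA for residue "
                               f"{atom.res_name!r} (atom {atom.name})")
        else:
            ref[i] = np.inf  # backbone atoms never act as source atoms
    contrib = np.where(side, sasa.atom_area / ref * h, 0.0)
    out = np.zeros(n)
    side_idx = np.flatnonzero(side)
    if len(side_idx) == 0:
        return out
    # both paths accumulate in ascending j order, so they agree bit-for-bit
    if brute_force:
        for i in range(n):
            for j in side_idx:
                if np.linalg.norm(coords[i] - coords[j]) < params.cutoff:  # strict <
                    out[i] += contrib[j]
        return out
    tree_all = cKDTree(coords)
    tree_side = cKDTree(coords[side_idx])
    for i, neigh in enumerate(tree_all.query_ball_tree(tree_side, params.cutoff)):
        for k in sorted(neigh):
            j = side_idx[k]
            if np.linalg.norm(coords[i] - coords[j]) < params.cutoff:  # strict <
                out[i] += contrib[j]
    return out


def sap_score(per_atom_sap: np.ndarray) -> float:
    """Total SAP score: sum of positive per-atom values."""
    v = np.asarray(per_atom_sap, dtype=float)
    return float(np.maximum(v, 0.0).sum())


def mlp_vertices(mesh: SurfaceMesh, structure: Structure, h: np.ndarray,
                 params: ScoringParams = ScoringParams()) -> SurfaceMesh:
    """Molecular lipophilicity potential at every mesh vertex (in place).

    MLP_k is the g-weighted average of atomic h over atoms within the cutoff,
    hence always bounded by the contributing atoms' min/max h.  A vertex with
    no atom in range (or a vanishing weight sum) gets 0 with a warning; that
    cannot happen for an SES vertex under the default cutoff, which exceeds the
    probe radius plus the largest vdW radius.
    """
    h = _check_aligned(structure, h)
    coords = structure.coords
    tree = cKDTree(coords)
    values = np.zeros(len(mesh.vertices))
    starved = 0
    neighbors = tree.query_ball_point(mesh.vertices, params.cutoff)
    for k, idx in enumerate(neighbors):
        if not idx:
            starved += 1
            continue
        idx = np.array(idx)
        r = np.linalg.norm(coords[idx] - mesh.vertices[k], axis=1)
        in_range = r < params.cutoff
        w = params.g(r[in_range])
        denom = w.sum()
        if denom < 1e-12:
            starved += 1
            continue
        values[k] = float(np.dot(w, h[idx[in_range]]) / denom)
    if starved:
        warnings.warn(f"{starved} mesh vertices had no atom within {params.cutoff} A "
                      "(MLP set to 0); is the mesh from this structure?")
    mesh.vertex_values = values
    return mesh


def heiden_score(mesh: SurfaceMesh) -> float:
    """Area-weighted sum of positive vertex MLP values."""
    if mesh.vertex_values is None:
        raise ValueError("mesh has no MLP values; call mlp_vertices first")
    return float(np.dot(np.maximum(mesh.vertex_values, 0.0), mesh.vertex_areas))


@dataclass
class FrameEnsemble:
    """Structures sampled from a (possibly boosted) MD trajectory.

    ``boost_energies`` holds, per frame, the boost-potential samples DeltaV in
    kcal/mol collected while that frame is representative; ``None`` means
    unbiased sampling (uniform weights).
    """

    frames: Sequence[Structure]
    boost_energies: Sequence[np.ndarray] | None = None
    temperature: float = 300.0

    def __post_init__(self):
        if not self.frames:
            raise ValueError("ensemble needs at least one frame")
        counts = {len(f.atoms) for f in self.frames}
        if len(counts) != 1:
            raise ValueError("all frames must share the same atom count")
        names = {tuple(a.name for a in f.atoms) for f in self.frames}
        if len(names) != 1:
            raise ValueError("all frames must share the same atom names")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.boost_energies is not None:
            if len(self.boost_energies) != len(self.frames):
                raise ValueError(f"{len(self.boost_energies)} boost-energy blocks for "
                                 f"{len(self.frames)} frames")
            self.boost_energies = [np.atleast_1d(np.asarray(b, dtype=float))
                                   for b in self.boost_energies]


def ensemble_weights(ensemble: FrameEnsemble) -> np.ndarray:
    """Frame weights from second-order cumulant reweighting of the boost energy.

    log w_f  proportional to  beta*mean(DeltaV_f) + beta^2/2 * var(DeltaV_f),
    with beta = 1/(k_B T); uniform if no boost energies are given.  Adding a
    constant to every DeltaV leaves the normalized weights unchanged.
    """
    n = len(ensemble.frames)
    if ensemble.boost_energies is None:
        return np.full(n, 1.0 / n)
    beta = 1.0 / (BOLTZMANN_KCAL * ensemble.temperature)
    logw = np.array([beta * b.mean() + 0.5 * beta ** 2 * b.var() for
                     b in ensemble.boost_energies])
    return np.exp(logw - logsumexp(logw))


def ensemble_score(ensemble: FrameEnsemble,
                   score_fn: Callable[[Structure], float]) -> float:
    """Reweighted ensemble average of a per-structure score."""
    w = ensemble_weights(ensemble)
    return float(sum(wf * score_fn(f) for wf, f in zip(w, ensemble.frames)))


METHODS = ("surf", "pos-surf", "sap", "heiden")


def score_structure(structure: Structure, scale, method: str,
                    params: ScoringParams = ScoringParams(),
                    sasa: SasaResult | None = None,
                    mesh: SurfaceMesh | None = None,
                    n_points: int = 960, grid_spacing: float = 0.5,
                    reference_areas: Mapping[str, float] | None = None) -> float:
    """Convenience front end: assign h, compute the needed geometry, score.

    Precomputed ``sasa`` / ``mesh`` may be passed to amortize geometry across
    scales; they must come from the same structure and parameters.
    """
    from .sasa import reference_sidechain_sasa, shrake_rupley
    from .scales import assign_hydrophobicity
    from .ses import build_distance_grid, extract_ses

    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    h = assign_hydrophobicity(structure, scale)
    if method in ("surf", "pos-surf", "sap"):
        if sasa is None:
            sasa = shrake_rupley(structure, probe_radius=params.probe_radius,
                                 n_points=n_points)
        if method == "surf":
            return surf_score(structure, sasa, h)
        if method == "pos-surf":
            return pos_surf_score(structure, sasa, h)
        if reference_areas is None:
            reference_areas = reference_sidechain_sasa()
        return sap_score(sap_per_atom(structure, sasa, h, reference_areas, params))
    if mesh is None:
        grid = build_distance_grid(structure, spacing=grid_spacing,
                                   probe_radius=params.probe_radius)
        mesh = extract_ses(grid, structure=structure)
    mlp_vertices(mesh, structure, h, params)
    return heiden_score(mesh)


def score_table(structures: Sequence[Structure], scale_names: Sequence[str],
                methods: Sequence[str] = METHODS,
                params: ScoringParams = ScoringParams(),
                n_points: int = 960, grid_spacing: float = 0.5) -> pd.DataFrame:
    """Score every structure with every (scale, method) combination.

    Returns a tidy frame with columns id, scale, method, score; geometry (SASA
    and SES mesh) is computed once per structure and shared across scales.
    """
    from .sasa import reference_sidechain_sasa, shrake_rupley
    from .scales import load_scale
    from .ses import build_distance_grid, extract_ses

    scales = [load_scale(s) for s in scale_names]
    ref = reference_sidechain_sasa()
    rows = []
    for st in structures:
        sasa = shrake_rupley(st, probe_radius=params.probe_radius, n_points=n_points)
        mesh = None
        if "heiden" in methods:
            grid = build_distance_grid(st, spacing=grid_spacing,
                                       probe_radius=params.probe_radius)
            mesh = extract_ses(grid, structure=st)
        for scale in scales:
            for method in methods:
                s = score_structure(st, scale, method, params=params, sasa=sasa,
                                    mesh=mesh, reference_areas=ref)
                rows.append({"id": st.label, "scale": scale.name,
                             "method": method, "score": s})
    df = pd.DataFrame(rows)
    if df.duplicated(["id", "scale", "method"]).any():
        raise ValueError("duplicate (id, scale, method) rows; structure labels must be unique")
    return df


def pearson_benchmark(scores: pd.DataFrame, experimental: Mapping[str, float],
                      min_matches: int = 3, rank: bool = False) -> pd.DataFrame:
    """Correlate scores with experimental retention per (scale, method).

    ``scores`` must have columns id, scale, method, score.  Ids present on only
    one side are logged, never silently dropped.  ``rank=True`` switches to
    Spearman (Pearson is the default and the reported statistic).
    """
    required = {"id", "scale", "method", "score"}
    if not required.issubset(scores.columns):
        raise ValueError(f"scores table needs columns {sorted(required)}")
    ids_scores = set(scores["id"])
    missing_exp = ids_scores - set(experimental)
    missing_scores = set(experimental) - ids_scores
    if missing_exp:
        logger.warning("no experimental value for ids: %s", sorted(missing_exp))
    if missing_scores:
        logger.warning("no scores for experimental ids: %s", sorted(missing_scores))
    rows = []
    for (scale, method), grp in scores.groupby(["scale", "method"], sort=False):
        grp = grp[grp["id"].isin(experimental)]
        if len(grp) < min_matches:
            raise ValueError(f"({scale}, {method}): only {len(grp)} matched ids; "
                             f"need >= {min_matches}")
        x = grp["score"].to_numpy(dtype=float)
        y = np.array([experimental[i] for i in grp["id"]], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"({scale}, {method}): zero variance; correlation undefined")
        r = (spearmanr(x, y).statistic if rank else pearsonr(x, y).statistic)
        rows.append({"scale": scale, "method": method, "pearson_r": float(r),
                     "n": len(grp)})
    return pd.DataFrame(rows)
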