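"""Solvent-excluded surface (SES) as a triangle mesh.

The SES is built in two passes.  First, grid points that a water-sized probe
centre may occupy are identified (distance >= vdw + probe from every atom
centre) and a Euclidean distance transform gives, for every grid point, the
distance to the nearest valid probe centre.  Second, the isosurface of that
field at the probe radius (1.4 A) is extracted with marching cubes: a point
exactly one probe radius away from the closest allowed probe centre lies on the
boundary the probe cannot cross, which is the solvent-excluded surface.  The
area of each triangle is split equally among its three vertices to give the
per-vertex areas used by surface-projection scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .structure import Structure


@dataclass(frozen=True)
class DistanceGrid:
    """Regular grid with, at every node, the distance to the nearest valid probe centre."""

    origin: np.ndarray       # (3,), Angstrom
    spacing: float           # Angstrom, isotropic
    field: np.ndarray        # (nx, ny, nz), Angstrom; 0 in bulk solvent
    probe_radius: float


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-vertex areas and an optional per-vertex scalar."""

    vertices: np.ndarray                 # (nv, 3) Angstrom
    triangles: np.ndarray                # (nt, 3) int vertex indices
    vertex_areas: np.ndarray             # (nv,) A^2
    vertex_values: np.ndarray | None = None   # e.g. per-vertex MLP

    def __post_init__(self):
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle indices out of range")

    @property
    def area(self) -> float:
        return float(self.vertex_areas.sum())

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def is_closed(self) -> bool:
        """True if every edge is shared by exactly two triangles."""
        edges = {}
        for tri in self.triangles:
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                edges[key] = edges.get(key, 0) + 1
        return bool(edges) and all(c == 2 for c in edges.values())


def build_distance_grid(structure: Structure, spacing: float = 0.5,
                        probe_radius: float = 1.4) -> DistanceGrid:
    """Distance-to-nearest-valid-probe-centre field on a padded regular grid.

    A grid point is a valid probe centre if it is at least (vdw + probe) from
    every atom centre.  The padding (max vdw + 2 probe + 2 spacing) guarantees
    the grid boundary is bulk solvent, so the extracted surface is closed.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    coords = structure.coords
    radii = structure.radii
    pad = radii.max() + 2.0 * probe_radius + 2.0 * spacing
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    # invalid = within (vdw + probe) of some atom; carve per atom on a local box
    invalid = np.zeros(shape, dtype=bool)
    for c, r in zip(coords, radii):
        reach = r + probe_radius
        i_lo = np.maximum(np.floor((c - reach - lo) / spacing).astype(int), 0)
        i_hi = np.minimum(np.ceil((c + reach - lo) / spacing).astype(int) + 1, shape)
        ax = [lo[d] + spacing * np.arange(i_lo[d], i_hi[d]) - c[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = invalid[i_lo[0]:i_hi[0], i_lo[1]:i_hi[1], i_lo[2]:i_hi[2]]
        sub |= d2 < reach ** 2
    dist = distance_transform_edt(invalid, sampling=spacing)
    dist = _refine_near_iso(dist, lo, spacing, coords, radii, probe_radius)
    return DistanceGrid(origin=lo, spacing=spacing, field=dist, probe_radius=probe_radius)


def _refine_near_iso(dist, origin, spacing, coords, radii, probe_radius):
    """Sub-voxel correction of the distance field near the extraction level.

    The voxelized transform measures distances to valid-probe voxel *centres*
    and so overestimates by a fraction of a voxel.  For a point x inside the
    union of inflated spheres, the penetration depth of the deepest sphere,
    v = max_a (vdw_a + probe - |x - c_a|), is a lower bound that is attained
    exactly whenever the radial projection out of that sphere is itself a valid
    probe centre (always true on locally convex surface).  Voxels within two
    spacings of the probe-radius level get the exact value where that test
    passes; re-entrant grooves keep the voxel-accurate transform.
    """
    from scipy.spatial import cKDTree

    reach = radii + probe_radius
    band = np.argwhere(np.abs(dist - probe_radius) <= 2.0 * spacing + 1e-9)
    if band.size == 0:
        return dist
    pts = origin + band * spacing
    tree = cKDTree(coords)
    neigh = tree.query_ball_point(pts, reach.max())
    for row, idx in zip(band, neigh):
        if not idx:
            continue
        x = origin + row * spacing
        idx = np.asarray(idx)
        pen = reach[idx] - np.linalg.norm(coords[idx] - x, axis=1)
        k = int(np.argmax(pen))
        v = pen[k]
        if v <= 0:
            continue
        a = idx[k]
        direction = x - coords[a]
        nrm = np.linalg.norm(direction)
        if nrm < 1e-9:
            continue
        q = coords[a] + direction * (reach[a] / nrm)
        others = tree.query_ball_point(q, reach.max())
        if all(np.linalg.norm(q - coords[b]) >= reach[b] - 1e-9 for b in others):
            dist[tuple(row)] = v
    return dist


def extract_ses(grid: DistanceGrid, level: float | None = None,
                largest_component: bool = False,
                structure: Structure | None = None,
                refine: bool = True) -> SurfaceMesh:
    """Extract the SES mesh as the isosurface of the distance field.

    ``level`` defaults to the probe radius.  Interior cavities produce separate
    closed components and are kept by default; ``largest_component=True`` keeps
    only the outer surface (largest total area component).

    Marching-cubes triangulations are inscribed in the true surface and so
    underestimate its area by O(spacing^2).  When ``structure`` is given and
    ``refine`` is true, one midpoint subdivision is applied and the new
    vertices are projected back onto the exact isosurface wherever the surface
    is locally convex, which removes most of that bias.
    """
    from skimage import measure

    if level is None:
        level = grid.probe_radius
    fmin, fmax = float(grid.field.min()), float(grid.field.max())
    if not (fmin < level < fmax):
        raise ValueError(f"iso level {level} outside field range [{fmin}, {fmax}]; "
                         "no surface to extract")
    verts, faces, _, _ = measure.marching_cubes(
        grid.field, level=level, spacing=(grid.spacing,) * 3)
    verts = verts + grid.origin
    if structure is not None and refine:
        verts, faces = _subdivide_project(verts, faces, structure, level,
                                          grid.probe_radius)
    mesh = SurfaceMesh(vertices=verts, triangles=faces,
                       vertex_areas=_vertex_areas(verts, faces))
    if largest_component:
        mesh = _largest_component(mesh)
    return mesh


def _subdivide_project(verts, faces, structure: Structure, level, probe_radius):
    """4-to-1 midpoint subdivision; project midpoints onto the exact isosurface.

    A midpoint m is moved radially onto the sphere of its deepest inflated atom
    at radius (vdw + probe - level) when the corresponding probe-centre
    projection is a valid probe position (locally convex surface); otherwise it
    stays on the chord (re-entrant grooves keep marching-cubes accuracy).
    """
    from scipy.spatial import cKDTree

    coords = structure.coords
    reach = structure.radii + probe_radius
    tree = cKDTree(coords)
    edge_mid: dict = {}
    new_verts = [verts]
    mid_pts = []

    def mid_index(a, b):
        key = (min(a, b), max(a, b))
        if key not in edge_mid:
            edge_mid[key] = len(verts) + len(mid_pts)
            mid_pts.append(0.5 * (verts[a] + verts[b]))
        return edge_mid[key]

    new_faces = []
    for t0, t1, t2 in faces:
        m01, m12, m20 = mid_index(t0, t1), mid_index(t1, t2), mid_index(t2, t0)
        new_faces += [(t0, m01, m20), (t1, m12, m01), (t2, m20, m12), (m01, m12, m20)]
    mids = np.array(mid_pts)
    if len(mids):
        neigh = tree.query_ball_point(mids, reach.max())
        rmax = reach.max()
        for k, idx in enumerate(neigh):
            if not idx:
                continue
            idx = np.asarray(idx)
            pen = reach[idx] - np.linalg.norm(coords[idx] - mids[k], axis=1)
            a = idx[int(np.argmax(pen))]
            direction = mids[k] - coords[a]
            nrm = np.linalg.norm(direction)
            if nrm < 1e-9:
                continue
            direction /= nrm
            q = coords[a] + direction * reach[a]
            others = tree.query_ball_point(q, rmax)
            if all(np.linalg.norm(q - coords[b]) >= reach[b] - 1e-9 for b in others):
                mids[k] = coords[a] + direction * (reach[a] - level)
        new_verts.append(mids)
    verts_out = np.vstack(new_verts) if len(mids) else verts
    return verts_out, np.array(new_faces, dtype=int)


def _vertex_areas(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    cross = np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                     verts[faces[:, 2]] - verts[faces[:, 0]])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(len(verts))
    for k in range(3):
        np.add.at(areas, faces[:, k], tri_area / 3.0)
    return areas


def _largest_component(mesh: SurfaceMesh) -> SurfaceMesh:
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    nv = len(mesh.vertices)
    e = np.concatenate([mesh.triangles[:, [0, 1]], mesh.triangles[:, [1, 2]],
                        mesh.triangles[:, [2, 0]]])
    adj = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(nv, nv))
    _, labels = connected_components(adj, directed=False)
    best = np.argmax([mesh.vertex_areas[labels == l].sum() for l in np.unique(labels)])
    keep = labels == np.unique(labels)[best]
    remap = -np.ones(nv, dtype=int)
    remap[keep] = np.arange(keep.sum())
    tri_keep = keep[mesh.triangles].all(axis=1)
    verts = mesh.vertices[keep]
    faces = remap[mesh.triangles[tri_keep]]
    return SurfaceMesh(vertices=verts, triangles=faces,
                       vertex_areas=_vertex_areas(verts, faces))


def write_obj(mesh: SurfaceMesh, path) -> None:
    """Export as Wavefront OBJ (geometry only)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for t in mesh.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def write_ply(mesh: SurfaceMesh, path) -> None:
    """Export as ASCII PLY; the per-vertex scalar is stored as property 'mlp'."""
    has_val = mesh.vertex_values is not None
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(mesh.vertices)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        if has_val:
            fh.write("property float mlp\n")
        fh.write(f"element face {len(mesh.triangles)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for i, v in enumerate(mesh.vertices):
            line = f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}"
            if has_val:
                line += f" {mesh.vertex_values[i]:.6f}"
            fh.write(line + "\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
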