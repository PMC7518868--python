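"""Synthetic spherical cortical geometry.

Real analyses of this kind run on a parcellated cortical surface (an
atlas of a few hundred regions per hemisphere, each region a connected
patch of a triangulated sheet, with spherical registration coordinates
for every parcel).  This module builds a self-contained stand-in: an
icosphere mesh split into left/right hemispheres at the x = 0 plane,
parcellated into Voronoi cells of a quasi-uniform (Fibonacci) point set,
with a small polar cap per pole excluded as a "medial wall" and two
seed-vertex sets per hemisphere playing the roles of the archicortical
(hippocampal) and paleocortical (piriform) origins of the dual-origin
model of cortical differentiation.

All downstream machinery (spin rotations, geodesic distance, parcel
aggregation) only requires what this geometry provides: unit-sphere
parcel centroids, hemisphere labels, a triangle mesh and a
vertex-to-parcel map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.cluster.vq import kmeans2
from scipy.spatial import cKDTree

MEDIAL_WALL = -1

# anchor directions (unit-normalized later) for the two dual-origin seed
# sets, per hemisphere: archicortex posterior-superior-medial, paleocortex
# anterior-inferior-medial; antipodal-ish by construction
_ARCHI_DIR = np.array([0.15, -0.40, 0.90])
_PALEO_DIR = np.array([0.15, 0.40, -0.90])


@dataclass
class ParcelGeometry:
    """Parcellated spherical surface.

    Attributes
    ----------
    parcel_ids : (p,) int array of parcel labels (0..p-1).
    hemisphere : (p,) array of 'L'/'R'.
    centroids : (p, 3) unit vectors, spherical parcel centroids.
    community : (p,) int labels in 1..C.
    mesh : trimesh.Trimesh, vertices in mm.
    vertex_to_parcel : (n_vertices,) int, parcel id or MEDIAL_WALL (-1).
    seed_points : mapping name -> vertex index array; contains
        'archicortex_L/R' and 'paleocortex_L/R'.
    radius_mm : sphere radius used for the mesh.
    """

    parcel_ids: np.ndarray
    hemisphere: np.ndarray
    centroids: np.ndarray
    community: np.ndarray
    mesh: trimesh.Trimesh
    vertex_to_parcel: np.ndarray
    seed_points: dict[str, np.ndarray] = field(default_factory=dict)
    radius_mm: float = 100.0

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def parcel_vertices(self, parcel: int) -> np.ndarray:
        return np.flatnonzero(self.vertex_to_parcel == parcel)

    def hemisphere_mask(self, hemi: str) -> np.ndarray:
        """Boolean parcel mask for hemisphere 'L' or 'R'."""
        return self.hemisphere == hemi

    def vertex_hemisphere(self) -> np.ndarray:
        """Per-vertex 'L'/'R' by sign of x (medial wall included)."""
        unit = self.mesh.vertices / np.linalg.norm(self.mesh.vertices, axis=1, keepdims=True)
        return np.where(unit[:, 0] < 0, "L", "R")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform point set on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian, det = +1)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_sphere_parcellation(
    n_parcels: int,
    mesh_resolution: int = 4,
    seed: int = 0,
    *,
    n_communities: int = 7,
    radius_mm: float = 100.0,
    medial_wall_angle: float = 0.25,
    seed_point_angle: float = 0.20,
) -> ParcelGeometry:
    """Build an icosphere parcellation with planted dual-origin seeds.

    Parcels are Voronoi cells of a randomly rotated Fibonacci lattice,
    restricted to the hemisphere (sign of x) of their lattice seed.
    Polar caps of angular radius ``medial_wall_angle`` (radians) around
    (0,0,±1) are excluded from every parcel, emulating a medial wall.
    Deterministic for fixed ``seed``.
    """
    if n_parcels < 4:
        raise ValueError("n_parcels must be >= 4")
    mesh = trimesh.creation.icosphere(subdivisions=mesh_resolution, radius=1.0)
    verts = np.asarray(mesh.vertices)
    n_vertices = len(verts)
    if n_vertices < 10 * n_parcels:
        raise ValueError(
            f"mesh_resolution={mesh_resolution} gives {n_vertices} vertices; "
            f"need >= {10 * n_parcels} for n_parcels={n_parcels}"
        )
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    seeds = fibonacci_sphere(n_parcels) @ rot.T
    # hemisphere membership by sign of x; retry rotations until both
    # hemispheres hold at least 2 parcels (essentially always immediate)
    for _ in range(100):
        left = seeds[:, 0] < 0
        if 2 <= left.sum() <= n_parcels - 2:
            break
        rot = _random_rotation(rng)
        seeds = fibonacci_sphere(n_parcels) @ rot.T

    polar_angle = np.minimum(
        np.arccos(np.clip(verts[:, 2], -1, 1)),
        np.arccos(np.clip(-verts[:, 2], -1, 1)),
    )
    medial = polar_angle < medial_wall_angle

    vertex_to_parcel = np.full(n_vertices, MEDIAL_WALL, dtype=int)
    vert_left = verts[:, 0] < 0
    # Voronoi assignment per hemisphere, followed by a few Lloyd
    # relaxation sweeps so cells clipped by the medial wall / hemisphere
    # boundary regain quasi-uniform size
    for hemi_mask_v, hemi_mask_s in ((vert_left, left), (~vert_left, ~left)):
        usable = hemi_mask_v & ~medial
        if not np.any(hemi_mask_s):
            continue
        s_idx = np.flatnonzero(hemi_mask_s)
        pts = verts[usable]
        cur = seeds[s_idx].copy()
        for _ in range(25):
            dist, nearest = cKDTree(cur).query(pts)
            nxt = cur.copy()
            for k in range(len(s_idx)):
                sel = pts[nearest == k]
                if len(sel):
                    c = sel.mean(axis=0)
                    nxt[k] = c / np.linalg.norm(c)
                else:
                    # empty-cell repair: reseed at the worst-covered vertex
                    nxt[k] = pts[int(np.argmax(dist))]
                    dist[int(np.argmax(dist))] = -1.0
            if np.allclose(nxt, cur, atol=1e-12):
                cur = nxt
                break
            cur = nxt
        _, nearest = cKDTree(cur).query(pts)
        vertex_to_parcel[np.flatnonzero(usable)] = s_idx[nearest]

    counts = np.bincount(vertex_to_parcel[vertex_to_parcel >= 0], minlength=n_parcels)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        raise ValueError(f"parcellation produced empty parcels: {empty.tolist()}")

    centroids = np.zeros((n_parcels, 3))
    for p in range(n_parcels):
        c = verts[vertex_to_parcel == p].mean(axis=0)
        centroids[p] = c / np.linalg.norm(c)

    # hemisphere follows the lattice seed's side (vertices were assigned
    # within-side, so centroids agree up to boundary jitter)
    hemisphere = np.where(left, "L", "R")

    # communities: k-means on centroids, labels 1..C
    n_comm = min(n_communities, n_parcels)
    _, labels = kmeans2(centroids, n_comm, minit="++", seed=int(rng.integers(2**31)))
    community = labels.astype(int) + 1

    seed_points: dict[str, np.ndarray] = {}
    for hemi, sign in (("L", -1.0), ("R", 1.0)):
        hemi_v = vert_left if hemi == "L" else ~vert_left
        for name, direction in (("archicortex", _ARCHI_DIR), ("paleocortex", _PALEO_DIR)):
            d = direction * np.array([sign, 1.0, 1.0])
            d = d / np.linalg.norm(d)
            ang = np.arccos(np.clip(verts @ d, -1, 1))
            sel = np.flatnonzero((ang < seed_point_angle) & hemi_v & ~medial)
            if sel.size == 0:  # fall back to single nearest usable vertex
                cand = np.flatnonzero(hemi_v & ~medial)
                sel = cand[[np.argmin(ang[cand])]]
            seed_points[f"{name}_{hemi}"] = sel

    mesh_mm = trimesh.Trimesh(vertices=verts * radius_mm, faces=mesh.faces, process=False)
    return ParcelGeometry(
        parcel_ids=np.arange(n_parcels),
        hemisphere=hemisphere,
        centroids=centroids,
        community=community,
        mesh=mesh_mm,
        vertex_to_parcel=vertex_to_parcel,
        seed_points=seed_points,
        radius_mm=radius_mm,
    )
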