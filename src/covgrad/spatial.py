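"""Spatial inference on parcellated spherical surfaces.

Covers geodesic distance on triangle meshes (graph shortest paths),
spin permutation tests (random rotations of the spherical coordinates,
mirrored across hemispheres, preserving spatial autocorrelation in the
null), the energy two-sample statistic with a permutation null,
distance-regressed covariance, correlation confidence intervals, and the
dual-origin association analysis (gradient vs. distance from the
archicortical and paleocortical origins).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import stats
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .geometry import MEDIAL_WALL, ParcelGeometry
from .matrices import SymmetricParcelMatrix

_MIRROR = np.diag([-1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# geodesic distance


def _edge_graph(mesh: trimesh.Trimesh, vertex_mask: np.ndarray | None = None):
    edges = mesh.edges_unique
    lengths = mesh.edges_unique_length
    if vertex_mask is not None:
        keep = vertex_mask[edges[:, 0]] & vertex_mask[edges[:, 1]]
        edges, lengths = edges[keep], lengths[keep]
    n = len(mesh.vertices)
    g = coo_matrix(
        (np.r_[lengths, lengths], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return g.tocsr()


def geodesic_distance(
    mesh: trimesh.Trimesh,
    sources: np.ndarray,
    vertex_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-vertex shortest-path distance from a source vertex set.

    Distances run along mesh edges weighted by Euclidean edge length
    (graph approximation to the exact polyhedral geodesic).  Vertices
    outside ``vertex_mask`` (if given) are excluded from the graph and
    reported as inf.
    """
    sources = np.atleast_1d(np.asarray(sources, dtype=int))
    if sources.size == 0:
        raise ValueError("empty source set")
    graph = _edge_graph(mesh, vertex_mask)
    d = dijkstra(graph, directed=False, indices=sources, min_only=True)
    reachable = np.isfinite(d)
    if vertex_mask is not None:
        expected = vertex_mask
    else:
        expected = np.ones(len(mesh.vertices), dtype=bool)
    if not np.all(reachable[expected]):
        n_unreach = int(np.sum(expected & ~reachable))
        raise ValueError(f"{n_unreach} vertices unreachable from sources (disconnected mesh region)")
    return d


@dataclass
class DistanceFields:
    """Per-parcel geodesic distances from the dual-origin seeds, plus the
    ipsilateral parcel-to-parcel distance matrix (NaN across hemispheres)."""

    archicortex_distance: np.ndarray
    paleocortex_distance: np.ndarray
    geodesic_matrix: SymmetricParcelMatrix | None = None


def distance_fields(
    geom: ParcelGeometry, include_matrix: bool = False
) -> DistanceFields:
    """Geodesic distance from the archi-/paleocortex seeds to every parcel.

    Distances are computed per hemisphere (ipsilateral only) and averaged
    over each parcel's vertices.  With ``include_matrix`` the p x p
    ipsilateral parcel distance matrix is computed as well: one Dijkstra
    run per parcel seeded at the vertex nearest its centroid, averaged
    over target-parcel vertices and symmetrized.
    """
    vert_hemi = geom.vertex_hemisphere()
    p = geom.n_parcels
    fields = {}
    for name in ("archicortex", "paleocortex"):
        out = np.full(p, np.nan)
        for hemi in ("L", "R"):
            mask = vert_hemi == hemi
            d = geodesic_distance(geom.mesh, geom.seed_points[f"{name}_{hemi}"], mask)
            for j in np.flatnonzero(geom.hemisphere == hemi):
                out[j] = d[geom.vertex_to_parcel == j].mean()
        fields[name] = out
    matrix = None
    if include_matrix:
        vals = np.full((p, p), np.nan)
        np.fill_diagonal(vals, 0.0)
        unit = geom.mesh.vertices / geom.radius_mm
        for hemi in ("L", "R"):
            mask = vert_hemi == hemi
            parcels = np.flatnonzero(geom.hemisphere == hemi)
            graph_mask = mask
            reps = []
            for j in parcels:
                verts = np.flatnonzero(geom.vertex_to_parcel == j)
                rep = verts[np.argmax(unit[verts] @ geom.centroids[j])]
                reps.append(rep)
            for a, j in enumerate(parcels):
                d = geodesic_distance(geom.mesh, np.array([reps[a]]), graph_mask)
                for b, k in enumerate(parcels):
                    if k == j:
                        continue
                    vals[j, k] = d[geom.vertex_to_parcel == k].mean()
        sym = np.where(np.isnan(vals) | np.isnan(vals.T), np.nan, (vals + vals.T) / 2.0)
        np.fill_diagonal(sym, 0.0)
        matrix = SymmetricParcelMatrix(
            values=sym, kind="distance", parcel_ids=geom.parcel_ids, meta={"ipsilateral_only": True}
        )
    return DistanceFields(
        archicortex_distance=fields["archicortex"],
        paleocortex_distance=fields["paleocortex"],
        geodesic_matrix=matrix,
    )


# ---------------------------------------------------------------------------
# spin permutation test


@dataclass
class SpinNull:
    n_rotations: int
    rotations: np.ndarray  # (n, 3, 3)
    permuted_assignments: np.ndarray  # (n, p) parcel -> parcel maps
    null_stats: np.ndarray = field(default_factory=lambda: np.empty(0))


def spin_permutations(
    geom: ParcelGeometry, n_rotations: int, seed: int, mode: str = "sphere"
) -> SpinNull:
    """Random-rotation parcel reassignments on the sphere.

    ``mode='sphere'`` (default): one uniform rotation of the whole sphere
    per iteration, each rotated parcel mapped to the nearest original
    centroid (duplicates allowed).  On this package's single-sphere
    geometry a whole-sphere rotation is an exact symmetry of any
    isotropic spatial process, which keeps the null well calibrated.

    ``mode='hemisphere'``: the convention used when each hemisphere is
    registered to its own sphere — rotation R applied to the left
    hemisphere, the x-mirrored conjugate M R M to the right, and
    reassignment restricted to ipsilateral centroids.
    """
    if mode not in ("sphere", "hemisphere"):
        raise ValueError("mode must be 'sphere' or 'hemisphere'")
    rng = np.random.default_rng(seed)
    p = geom.n_parcels
    rotations = np.empty((n_rotations, 3, 3))
    assignments = np.empty((n_rotations, p), dtype=int)
    if mode == "sphere":
        tree = cKDTree(geom.centroids)
        for i in range(n_rotations):
            r = stats.special_ortho_group.rvs(3, random_state=rng)
            rotations[i] = r
            _, nearest = tree.query(geom.centroids @ r.T)
            assignments[i] = nearest
    else:
        hemi_idx = {h: np.flatnonzero(geom.hemisphere == h) for h in ("L", "R")}
        trees = {h: cKDTree(geom.centroids[hemi_idx[h]]) for h in ("L", "R")}
        for i in range(n_rotations):
            r = stats.special_ortho_group.rvs(3, random_state=rng)
            rotations[i] = r
            for hemi in ("L", "R"):
                rot = r if hemi == "L" else _MIRROR @ r @ _MIRROR
                idx = hemi_idx[hemi]
                rotated = geom.centroids[idx] @ rot.T
                _, nearest = trees[hemi].query(rotated)
                assignments[i, idx] = idx[nearest]
    return SpinNull(n_rotations=n_rotations, rotations=rotations, permuted_assignments=assignments)


def spin_test(
    map_a: np.ndarray,
    map_b: np.ndarray,
    geom: ParcelGeometry,
    n_rotations: int = 1000,
    seed: int = 0,
    method: str = "pearson",
    null: SpinNull | None = None,
) -> tuple[float, float, SpinNull]:
    """Spin permutation test of the spatial correlation of two parcel maps.

    The null rotates map_a's parcels on the sphere (preserving its spatial
    autocorrelation) and recomputes the correlation with map_b; two-tailed
    p = (1 + #{|r_null| >= |r_obs|}) / (n_rotations + 1).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate map with zero variance")
    corr = _corr_func(method)
    r_obs = corr(a, b)
    if null is None:
        null = spin_permutations(geom, n_rotations, seed)
    null_stats = np.array([corr(a[perm], b) for perm in null.permuted_assignments])
    null.null_stats = null_stats
    p = (1 + np.sum(np.abs(null_stats) >= abs(r_obs))) / (null.n_rotations + 1)
    return float(r_obs), float(p), null


def _corr_func(method: str):
    if method == "pearson":
        return lambda x, y: float(np.corrcoef(x, y)[0, 1])
    if method == "spearman":
        return lambda x, y: float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# energy two-sample test


def energy_statistic(
    sample_a: np.ndarray, sample_b: np.ndarray, potential: str = "euclidean"
) -> float:
    """Energy distance E = 2 E|a-b| - E|a-a'| - E|b-b'| (Szekely-Rizzo).

    Within-sample means run over all ordered pairs (zero diagonal
    included), which makes E >= 0 with E = 0 iff the samples coincide as
    multisets.  ``potential='log'`` substitutes -log(d) pair potentials
    (the minimum-energy variant); its statistic is not sign-guaranteed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    a = a[:, None] if a.ndim == 1 else a
    b = b[:, None] if b.ndim == 1 else b
    dab = cdist(a, b)
    daa = cdist(a, a)
    dbb = cdist(b, b)
    if potential == "log":
        with np.errstate(divide="ignore"):
            f = lambda d: np.where(d > 0, -np.log(np.maximum(d, 1e-300)), 0.0)
        dab, daa, dbb = f(dab), f(daa), f(dbb)
    elif potential != "euclidean":
        raise ValueError("potential must be 'euclidean' or 'log'")
    return float(2.0 * dab.mean() - daa.mean() - dbb.mean())


def energy_test(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    potential: str = "euclidean",
) -> tuple[float, float]:
    """Permutation energy test: pooled relabeling, p = (1 + #{E_null >=
    E_obs}) / (n_perm + 1)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    a2 = a[:, None] if a.ndim == 1 else a
    b2 = b[:, None] if b.ndim == 1 else b
    n, m = len(a2), len(b2)
    pooled = np.vstack([a2, b2])
    d = cdist(pooled, pooled)
    if potential == "log":
        with np.errstate(divide="ignore"):
            d = np.where(d > 0, -np.log(np.maximum(d, 1e-300)), 0.0)

    def stat(idx_a: np.ndarray, idx_b: np.ndarray) -> float:
        return float(
            2.0 * d[np.ix_(idx_a, idx_b)].mean()
            - d[np.ix_(idx_a, idx_a)].mean()
            - d[np.ix_(idx_b, idx_b)].mean()
        )

    idx = np.arange(n + m)
    e_obs = stat(idx[:n], idx[n:])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n + m)
        if stat(perm[:n], perm[n:]) >= e_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return e_obs, float(p)


# ---------------------------------------------------------------------------
# distance regression and correlation CIs


def regress_distance(
    mat: SymmetricParcelMatrix, distances: SymmetricParcelMatrix
) -> SymmetricParcelMatrix:
    """Residualize a parcel matrix on geodesic distance and distance².

    OLS of the matrix entries on [1, d, d²] over all pairs with finite
    distance (ipsilateral pairs); entries without a distance (e.g.,
    cross-hemisphere) pass through unchanged.
    """
    v = mat.values.copy()
    d = distances.values
    p = v.shape[0]
    iu = np.triu_indices(p, k=1)
    dd = d[iu]
    ok = np.isfinite(dd)
    if ok.sum() < 3:
        raise ValueError("too few pairs with distances")
    x = np.column_stack([np.ones(ok.sum()), dd[ok], dd[ok] ** 2])
    if np.linalg.matrix_rank(x) < 3:
        raise ValueError("distance design rank deficient (constant distances)")
    y = v[iu][ok]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid_vals = v[iu].copy()
    resid_vals[ok] = y - x @ beta
    out = np.zeros_like(v)
    out[iu] = resid_vals
    out = out + out.T
    np.fill_diagonal(out, 0.0)
    return mat.copy_with(out, kind="covariance", distance_regressed=True)


def correlate_with_ci(
    map_a: np.ndarray,
    map_b: np.ndarray,
    method: str = "pearson",
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Correlation with a confidence interval.

    Pearson: Fisher z interval; Spearman: seeded bootstrap percentile
    interval.  A |r| = 1 interval is degenerate and returned as (r, r).
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("maps must have equal length >= 4")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate map with zero variance")
    r = _corr_func(method)(a, b)
    if abs(r) >= 1.0 - 1e-12:
        return float(r), float(r), float(r)
    if method == "pearson":
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(a.size - 3)
        zc = stats.norm.ppf(0.5 + ci_level / 2.0)
        return float(r), float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(a.size, size=a.size)
        boots[i] = stats.spearmanr(a[idx], b[idx]).statistic
    lo, hi = np.nanquantile(boots, [(1 - ci_level) / 2.0, 0.5 + ci_level / 2.0])
    return float(r), float(lo), float(hi)


# ---------------------------------------------------------------------------
# dual-origin association


@dataclass
class DualOriginReport:
    """Per origin (archicortex / paleocortex): the energy test comparing
    the origin-distance distributions of the two gradient halves, and the
    spin-tested linear association of the gradient with the distance map."""

    energy: dict  # origin -> (E, p)
    linear: dict  # origin -> (r, p_spin)
    split_point: float


def dual_origin_association(
    grad: np.ndarray,
    fields: DistanceFields,
    geom: ParcelGeometry,
    n_rotations: int = 1000,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "pearson",
) -> DualOriginReport:
    """Association between a gradient and the dual-origin distance fields.

    (i) splits parcels at the gradient median and energy-tests each
    origin's distance values between the halves; (ii) correlates the
    gradient with each distance map under a spin-test null.
    """
    grad = np.asarray(grad, dtype=float)
    median = float(np.median(grad))
    low = grad <= median
    high = ~low
    if high.sum() == 0:  # all values at the median
        order = np.argsort(grad, kind="stable")
        low = np.zeros(grad.size, dtype=bool)
        low[order[: grad.size // 2]] = True
        high = ~low
    null = spin_permutations(geom, n_rotations, seed)
    energy = {}
    linear = {}
    for k, (name, dist) in enumerate(
        (("archicortex", fields.archicortex_distance), ("paleocortex", fields.paleocortex_distance))
    ):
        e, pe = energy_test(dist[low], dist[high], n_perm=n_perm, seed=seed + 1 + k)
        energy[name] = (e, pe)
        r, ps, _ = spin_test(grad, dist, geom, method=method, null=null)
        linear[name] = (r, ps)
    return DualOriginReport(energy=energy, linear=linear, split_point=median)
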