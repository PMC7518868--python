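"""Equivolumetric intracortical surfaces and microstructural profile
covariance (MPC).

Equivolumetric surface placement compensates for cortical folding: the
Euclidean depth fraction rho of an intracortical surface varies with the
local outer/inner surface areas so that each lamina preserves its
fractional volume,

    rho = (1 / (A_out - A_in)) * (-A_in + sqrt(alpha*A_out^2 + (1-alpha)*A_in^2)),

with alpha the cumulative volume fraction.  Intensity profiles sampled
at these depths, averaged per parcel, yield a depths x parcels profile
matrix per subject; MPC between parcels i and j is the subject-averaged
partial correlation of their depth profiles controlling for the
cortex-wide mean profile:

    MPC(i, j) = mean_s (r_ij - r_ic * r_jc) / sqrt((1 - r_ic^2)(1 - r_jc^2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .geometry import MEDIAL_WALL, ParcelGeometry
from .matrices import SymmetricParcelMatrix

_EQUAL_AREA_RTOL = 1e-9


def equivolumetric_rho(alpha, A_out, A_in):
    """Euclidean depth fraction preserving fractional volume (vectorized).

    Boundary identities rho(0) = 0 and rho(1) = 1 hold exactly; the
    equal-area limit A_out -> A_in returns alpha (continuity extension).
    """
    alpha = np.asarray(alpha, dtype=float)
    A_out = np.asarray(A_out, dtype=float)
    A_in = np.asarray(A_in, dtype=float)
    if np.any(A_out <= 0) or np.any(A_in <= 0):
        raise ValueError("surface areas must be positive")
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("alpha must be in [0, 1]")
    diff = A_out - A_in
    equal = np.abs(diff) <= _EQUAL_AREA_RTOL * np.maximum(A_out, A_in)
    safe_diff = np.where(equal, 1.0, diff)
    rho = (-A_in + np.sqrt(alpha * A_out**2 + (1.0 - alpha) * A_in**2)) / safe_diff
    out = np.where(equal, alpha, rho)
    return float(out) if out.ndim == 0 else out


@dataclass
class ProfileMatrix:
    """n_surfaces x p parcel-mean intensities (arbitrary units)."""

    intensities: np.ndarray
    n_surfaces: int

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape[0] != self.n_surfaces:
            raise ValueError("intensities must have n_surfaces rows")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("profile intensities must be finite")


def vertex_onering_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Per-vertex one-ring (barycentric) areas: one third of each incident
    face's area accumulated at its vertices."""
    areas = np.zeros(len(mesh.vertices))
    fa = mesh.area_faces / 3.0
    np.add.at(areas, mesh.faces[:, 0], fa)
    np.add.at(areas, mesh.faces[:, 1], fa)
    np.add.at(areas, mesh.faces[:, 2], fa)
    return areas


def _pial_white_areas(geom: ParcelGeometry, thickness_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """One-ring areas of outer (pial) and inner (white) shells obtained by
    radially offsetting the mid-surface sphere by half the thickness."""
    verts = geom.mesh.vertices
    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    half = thickness_mm / 2.0
    outer = trimesh.Trimesh(vertices=verts + half * unit, faces=geom.mesh.faces, process=False)
    inner = trimesh.Trimesh(vertices=verts - half * unit, faces=geom.mesh.faces, process=False)
    return vertex_onering_areas(outer), vertex_onering_areas(inner)


def sample_profiles(
    intensity_field: np.ndarray,
    geom: ParcelGeometry,
    n_surfaces: int = 12,
    thickness_mm: float = 2.5,
) -> ProfileMatrix:
    """Sample an intensity field at equivolumetric depths, averaged per parcel.

    ``intensity_field`` is (n_depth_grid, n_vertices): intensity on a
    uniform Euclidean depth grid from the outer (row 0) to the inner
    surface (last row).  For each of ``n_surfaces`` volume fractions
    alpha (uniform in [0, 1]) the per-vertex equivolumetric depth rho is
    computed from the vertex one-ring areas of the outer/inner shells and
    the field is linearly interpolated at rho.
    """
    field = np.asarray(intensity_field, dtype=float)
    if n_surfaces < 2:
        raise ValueError("n_surfaces must be >= 2")
    if field.ndim != 2 or field.shape[1] != len(geom.mesh.vertices):
        raise ValueError("intensity_field must be (n_depth_grid, n_vertices)")
    if field.shape[0] < 2:
        raise ValueError("need at least 2 depth grid samples")
    if not np.all(np.isfinite(field)):
        raise ValueError("intensity field has missing depth samples")
    a_out, a_in = _pial_white_areas(geom, thickness_mm)
    alphas = np.linspace(0.0, 1.0, n_surfaces)
    n_vertices = field.shape[1]
    sampled = np.empty((n_surfaces, n_vertices))
    for s, alpha in enumerate(alphas):
        rho = equivolumetric_rho(np.full(n_vertices, alpha), a_out, a_in)
        # linear interpolation along the depth grid, per vertex
        pos = np.clip(rho, 0.0, 1.0) * (field.shape[0] - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, field.shape[0] - 1)
        w = pos - lo
        cols = np.arange(n_vertices)
        sampled[s] = (1 - w) * field[lo, cols] + w * field[hi, cols]
    p = geom.n_parcels
    profiles = np.empty((n_surfaces, p))
    for j in range(p):
        mask = geom.vertex_to_parcel == j
        profiles[:, j] = sampled[:, mask].mean(axis=1)
    return ProfileMatrix(intensities=profiles, n_surfaces=n_surfaces)


def make_intensity_field(
    geom: ParcelGeometry,
    n_depth_grid: int = 32,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic depth-resolved intensity field with parcel-class structure.

    Each community gets a template depth profile (a logistic ramp whose
    midpoint and slope vary by class, emulating laminar differences in a
    myelin-sensitive contrast); every vertex inherits its parcel's class
    template plus white noise.  Returns (field, class_labels) where field
    is (n_depth_grid, n_vertices) and class_labels is per-vertex (-1 on
    the medial wall).
    """
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, 1.0, n_depth_grid)
    classes = np.unique(geom.community)
    templates = {}
    for k, c in enumerate(classes):
        mid = 0.3 + 0.4 * k / max(len(classes) - 1, 1)
        slope = 6.0 + 2.0 * (k % 3)
        templates[c] = 1.0 / (1.0 + np.exp(-slope * (depth - mid)))
    n_vertices = len(geom.mesh.vertices)
    field = np.zeros((n_depth_grid, n_vertices))
    labels = np.full(n_vertices, MEDIAL_WALL)
    for j in range(geom.n_parcels):
        mask = geom.vertex_to_parcel == j
        c = geom.community[j]
        labels[mask] = c
        field[:, mask] = templates[c][:, None]
    field += noise_sd * rng.standard_normal(field.shape)
    return field, labels


def mpc_matrix(
    profiles: list[ProfileMatrix] | ProfileMatrix,
    parcel_ids: np.ndarray | None = None,
    fisher_z: bool = False,
) -> SymmetricParcelMatrix:
    """Microstructural profile covariance across subjects.

    Per subject: Pearson correlations r_ij between parcel depth profiles
    and r_ic with the cortex-wide mean profile c, combined into the
    partial correlation controlling c; subject matrices are averaged
    (optionally after Fisher z-transform, back-transformed).  Diagonal 1
    by convention; cells hitting |r_ic| = 1 are NaN.
    """
    if isinstance(profiles, ProfileMatrix):
        profiles = [profiles]
    if len(profiles) == 0:
        raise ValueError("need at least one subject")
    p = profiles[0].intensities.shape[1]
    if profiles[0].n_surfaces < 3:
        raise ValueError("need at least 3 surfaces for profile covariance")
    acc = np.zeros((p, p))
    count = np.zeros((p, p))
    for pm in profiles:
        x = pm.intensities  # depths x parcels
        c = x.mean(axis=1)
        aug = np.column_stack([x, c])
        r = np.corrcoef(aug, rowvar=False)
        r_ij = r[:p, :p]
        r_c = r[:p, p]
        denom = np.sqrt(np.clip((1 - r_c[:, None] ** 2) * (1 - r_c[None, :] ** 2), 0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            partial = (r_ij - np.outer(r_c, r_c)) / denom
        ok = denom > 1e-12
        vals = np.where(ok, partial, np.nan)
        if fisher_z:
            vals = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12))
        good = np.isfinite(vals)
        acc[good] += vals[good]
        count[good] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
    if fisher_z:
        mean = np.tanh(mean)
    mean = np.clip(mean, -1.0, 1.0)
    mean = (mean + mean.T) / 2.0
    np.fill_diagonal(mean, 1.0)
    ids = parcel_ids if parcel_ids is not None else np.arange(p)
    return SymmetricParcelMatrix(
        values=mean, kind="mpc", parcel_ids=ids, meta={"n_subjects": len(profiles), "fisher_z": fisher_z}
    )
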