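"""Macroscale gradient decomposition of parcel-by-parcel matrices.

Pipeline: row-wise sparsification of a covariance/correlation matrix
(keep the strongest fraction of each row), a normalized-angle similarity
kernel between the sparsified connectivity profiles, and diffusion map
embedding of the resulting affinity matrix.  The embedding axes
("gradients", unitless) order parcels by similarity of their covariance
profiles; helper operations bin a source matrix along a gradient and
align gradient sets across decompositions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csgraph, csr_matrix

from .matrices import SymmetricParcelMatrix


@dataclass
class GradientSet:
    """p x k embedding with eigenvalues and variance-explained fractions."""

    coords: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    alpha: float
    sparsity: float | None = None
    source_kind: str | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def threshold_rows(
    mat: SymmetricParcelMatrix | np.ndarray, keep_fraction: float = 0.10
) -> np.ndarray:
    """Row-wise top-fraction sparsification.

    Per row, retains the ``floor(keep_fraction * (p - 1))`` largest
    off-diagonal entries by signed value (ties broken toward the lower
    column index, deterministically) and zeroes the rest; the diagonal is
    preserved.  Returns a dense (generally asymmetric) array.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    v = mat.values if isinstance(mat, SymmetricParcelMatrix) else np.asarray(mat, dtype=float)
    p = v.shape[0]
    k = int(np.floor(keep_fraction * (p - 1)))
    if keep_fraction == 1.0:
        return v.copy()
    out = np.zeros_like(v)
    diag = np.diag(v).copy()
    for i in range(p):
        row = v[i].copy()
        row[i] = -np.inf
        # stable sort on -value: ties resolved toward lower column index
        order = np.argsort(-row, kind="stable")[:k]
        out[i, order] = v[i, order]
    np.fill_diagonal(out, diag)
    return out


def normalized_angle_affinity(sparse_mat: np.ndarray) -> np.ndarray:
    """Normalized-angle similarity between rows.

    affinity(i, j) = 1 - arccos(cosine(row_i, row_j)) / pi; symmetric,
    entries in [0, 1], diagonal 1.  Rows are the (possibly asymmetric)
    sparsified connectivity profiles.
    """
    v = np.asarray(sparse_mat, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(f"all-zero rows for parcels: {zero.tolist()}")
    cos = (v @ v.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = (aff + aff.T) / 2.0
    np.fill_diagonal(aff, 1.0)
    return np.clip(aff, 0.0, 1.0)


def _sign_fix(coords: np.ndarray) -> np.ndarray:
    """Deterministic per-component sign: non-negative correlation with the
    parcel-order index (falling back to a positive max-|value| entry)."""
    p = coords.shape[0]
    anchor = np.arange(p) - (p - 1) / 2.0
    out = coords.copy()
    for k in range(coords.shape[1]):
        c = float(anchor @ out[:, k])
        if c < 0:
            out[:, k] *= -1
        elif c == 0 and out[np.argmax(np.abs(out[:, k])), k] < 0:
            out[:, k] *= -1
    return out


def diffusion_embedding(
    affinity: np.ndarray | SymmetricParcelMatrix,
    n_components: int = 10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
    seed: int | None = None,
) -> GradientSet:
    """Diffusion map embedding of a non-negative affinity matrix.

    Density-normalizes W_alpha = D^-alpha W D^-alpha, row-normalizes to a
    Markov operator, and eigendecomposes (dense, via the symmetric
    conjugate).  Gradients are the nontrivial right eigenvectors scaled
    by lambda/(1 - lambda) at diffusion_time 0 and lambda**t otherwise;
    variance_explained is each nontrivial eigenvalue over the sum of
    positive nontrivial eigenvalues.  Deterministic; per-component signs
    fixed by a documented convention.
    """
    src_kind = None
    if isinstance(affinity, SymmetricParcelMatrix):
        src_kind = affinity.meta.get("source_kind", affinity.kind)
        affinity = affinity.values
    w = np.asarray(affinity, dtype=float)
    p = w.shape[0]
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_comp_graph, labels = csgraph.connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes.tolist()}")
    d0 = w.sum(axis=1)
    w_alpha = w / np.outer(d0**alpha, d0**alpha)
    d1 = w_alpha.sum(axis=1)
    s = w_alpha / np.sqrt(np.outer(d1, d1))
    s = (s + s.T) / 2.0
    evals, evecs = np.linalg.eigh(s)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    psi = evecs / np.sqrt(d1)[:, None]
    # normalize against the trivial (constant) eigenvector
    psi = psi / psi[:, [0]]
    k = min(n_components, p - 1)
    lam = evals[1 : k + 1]
    if diffusion_time == 0:
        scale = lam / (1.0 - np.clip(lam, None, 1.0 - 1e-12))
    else:
        scale = lam**diffusion_time
    coords = psi[:, 1 : k + 1] * scale
    coords = _sign_fix(coords)
    nontrivial = evals[1:]
    pos = nontrivial[nontrivial > 0]
    total = pos.sum() if pos.size else 1.0
    var_exp = np.clip(lam, 0, None) / total
    return GradientSet(
        coords=coords,
        eigenvalues=lam,
        variance_explained=var_exp,
        alpha=alpha,
        source_kind=src_kind,
    )


def gradients_from_matrix(
    mat: SymmetricParcelMatrix,
    n_components: int = 10,
    keep_fraction: float = 0.10,
    alpha: float = 0.5,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Full pipeline: threshold -> normalized-angle affinity -> embedding."""
    sparse = threshold_rows(mat, keep_fraction)
    aff = normalized_angle_affinity(sparse)
    gs = diffusion_embedding(aff, n_components=n_components, alpha=alpha, diffusion_time=diffusion_time)
    gs.sparsity = keep_fraction
    gs.source_kind = mat.kind
    return gs


@dataclass
class GradientBins:
    n_bins: int
    assignment: np.ndarray  # parcel -> bin in 1..n_bins
    bin_matrix: np.ndarray  # n_bins x n_bins mean source values


def bin_gradient(
    grad: np.ndarray, source: SymmetricParcelMatrix | np.ndarray, n_bins: int = 10
) -> GradientBins:
    """Cut a gradient into near-equal rank bins and average source values
    within/between bins (diagonal excluded within bins)."""
    grad = np.asarray(grad, dtype=float)
    p = grad.size
    if n_bins > p:
        raise ValueError("n_bins cannot exceed the number of parcels")
    v = source.values if isinstance(source, SymmetricParcelMatrix) else np.asarray(source)
    order = np.argsort(grad, kind="stable")
    assignment = np.empty(p, dtype=int)
    # near-equal bin sizes: sizes differ by at most 1
    splits = np.array_split(order, n_bins)
    for b, idx in enumerate(splits):
        assignment[idx] = b + 1
    bm = np.empty((n_bins, n_bins))
    for a in range(n_bins):
        ia = splits[a]
        for b in range(a, n_bins):
            ib = splits[b]
            block = v[np.ix_(ia, ib)]
            if a == b:
                mask = ~np.eye(len(ia), dtype=bool)
                bm[a, b] = block[mask].mean() if mask.any() else np.nan
            else:
                bm[a, b] = bm[b, a] = block.mean()
    return GradientBins(n_bins=n_bins, assignment=assignment, bin_matrix=bm)


@dataclass
class GradientAlignment:
    matching: list[tuple[int, int]]  # (column in a, column in b)
    correlations: np.ndarray  # signed r after optimal sign flip, per match
    sign_flips: np.ndarray


def align_gradients(a: GradientSet, b: GradientSet) -> GradientAlignment:
    """Greedy matching of gradient columns by maximal |Pearson r|.

    Repeatedly pairs the remaining columns with the largest absolute
    correlation; reports the signed correlation after flipping b's column
    to make it non-negative.
    """
    if a.coords.shape[0] != b.coords.shape[0]:
        raise ValueError("gradient sets are over different parcel sets")
    ka, kb = a.coords.shape[1], b.coords.shape[1]
    r = np.corrcoef(a.coords.T, b.coords.T)[:ka, ka:]
    matching: list[tuple[int, int]] = []
    corrs = []
    flips = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    absr = np.abs(r)
    for _ in range(min(ka, kb)):
        masked = absr.copy()
        if used_a:
            masked[list(used_a), :] = -1
        if used_b:
            masked[:, list(used_b)] = -1
        i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
        used_a.add(int(i))
        used_b.add(int(j))
        matching.append((int(i), int(j)))
        sign = 1.0 if r[i, j] >= 0 else -1.0
        flips.append(sign)
        corrs.append(abs(r[i, j]))
    return GradientAlignment(
        matching=matching, correlations=np.array(corrs), sign_flips=np.array(flips)
    )
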