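import numpy as np
import pytest

import covgrad as cg
from covgrad.gradients import _sign_fix
from covgrad.matrices import SymmetricParcelMatrix


def _random_corr(p, rng):
    x = rng.normal(size=(4 * p, p))
    c = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# row thresholding


def test_keep_all_leaves_matrix_unchanged(rng):
    v = _random_corr(20, rng)
    assert np.array_equal(cg.threshold_rows(v, 1.0), v)


def test_row_retention_count_at_default_cutoff(rng):
    v = _random_corr(400, rng)
    out = cg.threshold_rows(v, 0.10)
    k = int(np.floor(0.10 * 399))
    off = out - np.diag(np.diag(out))
    assert np.all((off != 0).sum(axis=1) == k)


def test_retained_entries_match_sort_oracle(rng):
    v = rng.normal(size=(30, 30))
    v = (v + v.T) / 2
    out = cg.threshold_rows(v, 0.2)
    k = int(np.floor(0.2 * 29))
    for i in range(30):
        row = v[i].copy()
        row[i] = -np.inf
        top = set(np.argsort(-row, kind="stable")[:k])
        kept = set(np.flatnonzero(out[i]) ) - {i}
        assert kept == top


def test_invalid_keep_fraction(rng):
    with pytest.raises(ValueError):
        cg.threshold_rows(_random_corr(10, rng), 0.0)


# ---------------------------------------------------------------------------
# normalized-angle affinity


def test_affinity_of_identical_orthogonal_antiparallel_rows():
    rows = np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 1.0],
            [-1.0, -1.0, 0.0, 0.0],
        ]
    )
    aff = cg.normalized_angle_affinity(rows)
    assert aff[0, 1] == pytest.approx(1.0)
    assert aff[0, 2] == pytest.approx(0.5)
    assert aff[0, 3] == pytest.approx(0.0, abs=1e-6)
    assert np.all((aff >= 0) & (aff <= 1))
    assert np.allclose(np.diag(aff), 1.0)


def test_zero_row_rejected():
    rows = np.eye(4)
    rows[2] = 0
    with pytest.raises(ValueError, match="2"):
        cg.normalized_angle_affinity(rows)


# ---------------------------------------------------------------------------
# diffusion embedding


def _ring_affinity(p, width=2):
    idx = np.arange(p)
    d = np.abs(idx[:, None] - idx[None, :])
    d = np.minimum(d, p - d)
    return np.exp(-0.5 * (d / width) ** 2)


def test_ring_graph_embeds_on_a_circle():
    p = 64
    gs = cg.diffusion_embedding(_ring_affinity(p), n_components=2)
    xy = gs.coords[:, :2]
    # circulant symmetry: first two components are a cos/sin pair, so the
    # angular order around the circle matches the ring order
    ang = np.unwrap(np.arctan2(xy[:, 1], xy[:, 0]))
    diffs = np.diff(ang)
    assert np.all(diffs > 0) or np.all(diffs < 0)
    radii = np.linalg.norm(xy, axis=1)
    assert radii.std() / radii.mean() < 1e-6


def test_two_block_affinity_separates_blocks_in_g1():
    p = 40
    aff = np.full((p, p), 0.05)
    aff[:20, :20] = 0.9
    aff[20:, 20:] = 0.9
    np.fill_diagonal(aff, 1.0)
    gs = cg.diffusion_embedding(aff, n_components=2)
    g1 = gs.coords[:, 0]
    assert np.ptp(np.sign(g1[:20])) == 0 and np.ptp(np.sign(g1[20:])) == 0
    assert np.sign(g1[0]) != np.sign(g1[-1])


def test_embedding_matches_dense_markov_oracle(rng):
    """Independent oracle: explicit Markov operator eigendecomposition."""
    w = _random_corr(60, rng)
    w = np.abs(w)
    alpha = 0.5
    gs = cg.diffusion_embedding(w, n_components=5, alpha=alpha)
    # oracle: form P directly and use scipy.linalg.eig
    from scipy.linalg import eig

    d0 = w.sum(1)
    w_a = w / np.outer(d0**alpha, d0**alpha)
    p_op = w_a / w_a.sum(1)[:, None]
    evals, evecs = eig(p_op)
    order = np.argsort(-evals.real)
    evals = evals.real[order]
    evecs = evecs.real[:, order]
    assert np.allclose(evals[1:6], gs.eigenvalues, atol=1e-8)
    for k in range(5):
        v = evecs[:, k + 1]
        u = gs.coords[:, k]
        r = abs(np.corrcoef(u, v)[0, 1])
        assert r > 1 - 1e-8


def test_markov_rows_sum_to_one(rng):
    w = np.abs(_random_corr(30, rng))
    d0 = w.sum(1)
    w_a = w / np.outer(np.sqrt(d0), np.sqrt(d0))
    p_op = w_a / w_a.sum(1)[:, None]
    assert np.allclose(p_op.sum(1), 1.0, atol=1e-12)


def test_eigenvalues_non_increasing_and_variance_fractions(rng):
    w = np.abs(_random_corr(50, rng))
    gs = cg.diffusion_embedding(w, n_components=8)
    assert np.all(np.diff(gs.eigenvalues) <= 1e-12)
    assert gs.variance_explained.sum() <= 1 + 1e-12
    assert np.all(gs.variance_explained >= 0)


def test_embedding_invariant_to_parcel_reordering(rng):
    w = np.abs(_random_corr(40, rng))
    perm = rng.permutation(40)
    a = cg.diffusion_embedding(w, n_components=3)
    b = cg.diffusion_embedding(w[np.ix_(perm, perm)], n_components=3)
    for k in range(3):
        r = abs(np.corrcoef(a.coords[perm, k], b.coords[:, k])[0, 1])
        assert r > 1 - 1e-8


def test_disconnected_affinity_rejected():
    w = np.eye(10)
    with pytest.raises(ValueError, match="disconnected"):
        cg.diffusion_embedding(w, n_components=2)


def test_sign_convention_deterministic(rng):
    coords = rng.normal(size=(50, 3))
    fixed = _sign_fix(coords)
    assert np.array_equal(_sign_fix(fixed), fixed)
    assert np.array_equal(np.abs(fixed), np.abs(coords))


# ---------------------------------------------------------------------------
# gradient bins


def test_ten_bins_of_400_parcels_have_40_each(rng):
    grad = rng.normal(size=400)
    src = _random_corr(400, rng)
    bins = cg.bin_gradient(grad, src, n_bins=10)
    counts = np.bincount(bins.assignment, minlength=11)[1:]
    assert np.all(counts == 40)


def test_identity_source_gives_zero_off_diagonal_bins(rng):
    grad = rng.normal(size=40)
    bins = cg.bin_gradient(grad, np.eye(40), n_bins=4)
    off = bins.bin_matrix[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 0.0)


def test_two_block_source_binning_matches_hand_oracle(rng):
    p = 40
    grad = np.arange(p, dtype=float)
    src = np.full((p, p), -0.2)
    src[:20, :20] = 0.8
    src[20:, 20:] = 0.8
    np.fill_diagonal(src, 1.0)
    bins = cg.bin_gradient(grad, src, n_bins=2)
    # hand-binned: bin1 = parcels 0..19, bin2 = 20..39
    b11 = src[:20, :20][~np.eye(20, dtype=bool)].mean()
    b12 = src[:20, 20:].mean()
    assert bins.bin_matrix[0, 0] == pytest.approx(b11)
    assert bins.bin_matrix[0, 1] == pytest.approx(b12)
    assert bins.bin_matrix[0, 0] > bins.bin_matrix[0, 1]


# ---------------------------------------------------------------------------
# gradient alignment


def _gset(coords):
    k = coords.shape[1]
    return cg.GradientSet(
        coords=coords,
        eigenvalues=np.linspace(1, 0.5, k),
        variance_explained=np.full(k, 1.0 / k),
        alpha=0.5,
    )


def test_alignment_recovers_sign_flips(rng):
    a = _gset(rng.normal(size=(100, 3)))
    b = _gset(a.coords * np.array([1, -1, 1]))
    rep = cg.align_gradients(a, b)
    assert rep.matching == [(0, 0), (1, 1), (2, 2)]
    assert np.allclose(rep.correlations, 1.0)


def test_alignment_recovers_column_permutation(rng):
    a = _gset(rng.normal(size=(100, 4)))
    perm = [2, 0, 3, 1]
    b = _gset(a.coords[:, perm])
    rep = cg.align_gradients(a, b)
    recovered = dict(rep.matching)
    for j_b, j_a in enumerate(perm):
        assert recovered[j_a] == j_b
    assert np.allclose(rep.correlations, 1.0)


def test_independent_gradient_sets_align_weakly():
    weak = 0
    for s in range(20):
        r = np.random.default_rng(s)
        a = _gset(r.normal(size=(400, 2)))
        b = _gset(r.normal(size=(400, 2)))
        rep = cg.align_gradients(a, b)
        weak += rep.correlations.max() < 0.2
    assert weak >= 18


def test_dimension_mismatch_rejected(rng):
    a = _gset(rng.normal(size=(50, 2)))
    b = _gset(rng.normal(size=(40, 2)))
    with pytest.raises(ValueError):
        cg.align_gradients(a, b)
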