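import numpy as np
import pytest
import trimesh

import covgrad as cg
from covgrad.matrices import SymmetricParcelMatrix
from covgrad.spatial import energy_statistic, spin_permutations


# ---------------------------------------------------------------------------
# geodesic distance


def test_single_triangle_distances_are_edge_lengths():
    mesh = trimesh.Trimesh(
        vertices=[[0, 0, 0], [3, 0, 0], [0, 4, 0]], faces=[[0, 1, 2]], process=False
    )
    d = cg.geodesic_distance(mesh, np.array([0]))
    assert d[0] == 0
    assert d[1] == pytest.approx(3.0)
    assert d[2] == pytest.approx(4.0)


def test_icosphere_antipodal_distance_close_to_pi():
    mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    src = int(np.argmax(mesh.vertices[:, 2]))
    d = cg.geodesic_distance(mesh, np.array([src]))
    # graph geodesics overestimate great-circle length slightly
    assert d.max() == pytest.approx(np.pi, rel=0.05)


def test_source_set_covering_all_vertices_gives_zero(geom_small):
    d = cg.geodesic_distance(geom_small.mesh, np.arange(len(geom_small.mesh.vertices)))
    assert np.allclose(d, 0.0)


def test_distance_fields_zero_at_seeds_and_ipsilateral(geom_small):
    fields = cg.distance_fields(geom_small, include_matrix=True)
    for name, arr in (
        ("archicortex", fields.archicortex_distance),
        ("paleocortex", fields.paleocortex_distance),
    ):
        assert np.all(np.isfinite(arr))
        assert np.all(arr >= 0)
    gm = fields.geodesic_matrix.values
    hemi = geom_small.hemisphere
    cross = hemi[:, None] != hemi[None, :]
    assert np.all(np.isnan(gm[cross]))
    same_off = ~cross & ~np.eye(len(hemi), dtype=bool)
    assert np.all(gm[same_off] > 0)
    assert np.allclose(np.diag(gm), 0.0)


# ---------------------------------------------------------------------------
# spin test


def test_spin_null_preserves_value_multiset(geom_small, rng):
    a = rng.normal(size=geom_small.n_parcels)
    null = spin_permutations(geom_small, 20, seed=4)
    for perm in null.permuted_assignments:
        assert set(np.unique(a[perm])) <= set(np.unique(a))
    # rotations orthogonal with det +1
    for r in null.rotations:
        assert np.allclose(r @ r.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0)


def test_identical_maps_give_minimal_spin_p(geom_small, rng):
    a = rng.normal(size=geom_small.n_parcels) + geom_small.centroids[:, 1]
    r, p, null = cg.spin_test(a, a, geom_small, n_rotations=99, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 100)


def test_spin_test_deterministic(geom_small, rng):
    a = rng.normal(size=geom_small.n_parcels)
    b = rng.normal(size=geom_small.n_parcels)
    r1, p1, _ = cg.spin_test(a, b, geom_small, n_rotations=50, seed=7)
    r2, p2, _ = cg.spin_test(a, b, geom_small, n_rotations=50, seed=7)
    assert (r1, p1) == (r2, p2)


def test_degenerate_map_rejected(geom_small):
    with pytest.raises(ValueError, match="zero variance"):
        cg.spin_test(
            np.zeros(geom_small.n_parcels),
            np.arange(geom_small.n_parcels, dtype=float),
            geom_small,
            n_rotations=10,
        )


# ---------------------------------------------------------------------------
# energy test


def test_energy_zero_for_identical_samples(rng):
    a = rng.normal(size=50)
    assert energy_statistic(a, a.copy()) == pytest.approx(0.0, abs=1e-12)


def test_energy_nonnegative_for_random_samples(rng):
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 30))
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), size=rng.integers(2, 30))
        assert energy_statistic(a, b) >= -1e-12


def test_separated_samples_give_minimal_p(rng):
    a = rng.normal(0, 1, 100)
    b = rng.normal(5, 1, 100)
    e, p = cg.energy_test(a, b, n_perm=1000, seed=3)
    assert e > 0
    assert p == pytest.approx(1 / 1001)


def test_energy_null_p_values_roughly_uniform():
    ps = []
    for s in range(100):
        r = np.random.default_rng(500 + s)
        a = r.normal(size=40)
        b = r.normal(size=40)
        _, p = cg.energy_test(a, b, n_perm=99, seed=s)
        ps.append(p)
    from scipy import stats

    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_single_element_sample_allowed(rng):
    e, p = cg.energy_test(np.array([1.0]), rng.normal(size=20), n_perm=100, seed=0)
    assert np.isfinite(e) and 0 < p <= 1


# ---------------------------------------------------------------------------
# distance regression


def _dist_matrix(p, rng):
    d = np.abs(rng.normal(2, 1, (p, p)))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return SymmetricParcelMatrix(d, "distance", np.arange(p))


def test_quadratic_distance_relation_removed_exactly(rng):
    p = 20
    dist = _dist_matrix(p, rng)
    d = dist.values
    cov_vals = 0.5 - 0.1 * d + 0.02 * d**2
    np.fill_diagonal(cov_vals, 1.0)
    mat = SymmetricParcelMatrix(np.clip(cov_vals, -1, 1), "covariance", np.arange(p))
    resid = cg.regress_distance(mat, dist)
    off = resid.values[~np.eye(p, dtype=bool)]
    assert np.max(np.abs(off)) < 1e-10


def test_distance_regression_residuals_orthogonal(rng):
    p = 25
    dist = _dist_matrix(p, rng)
    c = np.corrcoef(rng.normal(size=(40, p)), rowvar=False)
    mat = SymmetricParcelMatrix(c, "covariance", np.arange(p))
    resid = cg.regress_distance(mat, dist)
    iu = np.triu_indices(p, k=1)
    x = np.column_stack([np.ones(len(iu[0])), dist.values[iu], dist.values[iu] ** 2])
    assert np.max(np.abs(x.T @ resid.values[iu])) < 1e-8


def test_constant_distances_rejected(rng):
    p = 10
    d = np.ones((p, p)) - np.eye(p)
    dist = SymmetricParcelMatrix(d, "distance", np.arange(p))
    c = np.corrcoef(rng.normal(size=(30, p)), rowvar=False)
    mat = SymmetricParcelMatrix(c, "covariance", np.arange(p))
    with pytest.raises(ValueError, match="rank"):
        cg.regress_distance(mat, dist)


# ---------------------------------------------------------------------------
# correlation with CI


def test_fisher_z_interval_matches_textbook_formula(rng):
    # build maps with sample r ~ 0.5 at n = 403
    n = 403
    x = rng.normal(size=n)
    y = 0.5 * x + np.sqrt(1 - 0.25) * rng.normal(size=n)
    r, lo, hi = cg.correlate_with_ci(x, y, method="pearson")
    z = np.arctanh(r)
    se = 1 / np.sqrt(n - 3)
    assert lo == pytest.approx(np.tanh(z - 1.959963984540054 * se), abs=1e-10)
    assert hi == pytest.approx(np.tanh(z + 1.959963984540054 * se), abs=1e-10)
    # with r near 0.5, the interval brackets roughly (0.42, 0.57)
    assert 0.3 < lo < r < hi < 0.7


def test_perfect_correlation_degenerate_ci(rng):
    x = rng.normal(size=30)
    r, lo, hi = cg.correlate_with_ci(x, 2 * x + 1)
    assert r == pytest.approx(1.0) and lo == r and hi == r
    r2, *_ = cg.correlate_with_ci(x, -x)
    assert r2 == pytest.approx(-1.0)


def test_spearman_bootstrap_interval_brackets_estimate(rng):
    x = rng.normal(size=100)
    y = x + rng.normal(0, 1, 100)
    r, lo, hi = cg.correlate_with_ci(x, y, method="spearman", seed=5)
    assert lo < r < hi


# ---------------------------------------------------------------------------
# dual-origin association


def test_gradient_equal_to_distance_field_maximally_associated(geom_small):
    fields = cg.distance_fields(geom_small)
    rep = cg.dual_origin_association(
        fields.paleocortex_distance, fields, geom_small, n_rotations=60, n_perm=120, seed=2
    )
    r, p_spin = rep.linear["paleocortex"]
    assert r == pytest.approx(1.0)
    e, p_e = rep.energy["paleocortex"]
    assert e > 0 and p_e < 0.05


def test_planted_axis_recovered_against_paleo_distance():
    # inferior-superior axis and paleocortex distance share the z direction
    geom = cg.make_sphere_parcellation(80, 4, seed=21)
    fields = cg.distance_fields(geom)
    g2 = geom.centroids[:, 2]
    r, _, _ = cg.spin_test(g2, fields.paleocortex_distance, geom, n_rotations=30, seed=1)
    assert abs(r) > 0.6
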