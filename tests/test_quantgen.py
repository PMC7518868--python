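import numpy as np
import pandas as pd
import pytest
from scipy import stats

import covgrad as cg
from covgrad import quantgen as qg


def _twin_pedigree(n_mz, n_dz, n_single=0):
    rows = []
    fam = 0
    i = 0
    for zyg, n in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n):
            for _k in range(2):
                rows.append((f"S{i}", f"F{fam}", zyg, 30.0, i % 2, 0))
                i += 1
            fam += 1
    for _ in range(n_single):
        rows.append((f"S{i}", f"F{fam}", "singleton", 30.0, i % 2, 0))
        i += 1
        fam += 1
    return pd.DataFrame(rows, columns=["subject_id", "family_id", "zygosity", "age", "sex", "site"])


def _simulate_trait(ped, h2, rng):
    z = ped.zygosity.to_numpy()
    n = len(ped)
    x = np.empty(n)
    i = 0
    while i < n:
        if z[i] in ("MZ", "DZ"):
            a1 = rng.normal(0, np.sqrt(h2))
            if z[i] == "MZ":
                a2 = a1
            else:
                a2 = 0.5 * a1 + np.sqrt(3) / 2 * rng.normal(0, np.sqrt(h2))
            x[i] = a1 + rng.normal(0, np.sqrt(1 - h2))
            x[i + 1] = a2 + rng.normal(0, np.sqrt(1 - h2))
            i += 2
        else:
            x[i] = rng.normal(0, 1)
            i += 1
    return x


# ---------------------------------------------------------------------------
# inverse normal transform


def test_int_is_monotone_and_nearly_identity_on_normal_data(rng):
    x = rng.standard_normal(2000)
    y = cg.inverse_normal_transform(x)
    assert np.all(np.diff(y[np.argsort(x, kind="stable")]) >= 0)
    assert np.corrcoef(x, y)[0, 1] > 0.99
    assert abs(y.mean()) < 0.01
    assert abs(y.std() - 1) < 0.05


def test_int_blom_quantiles_for_three_values():
    # ranks 1,2,3 with Blom offset: Phi^-1((r - 3/8) / 3.25)
    y = cg.inverse_normal_transform(np.array([10.0, -5.0, 3.0]))
    expect = stats.norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
    assert np.allclose(y, expect)


def test_int_rejects_degenerate_input():
    with pytest.raises(ValueError):
        cg.inverse_normal_transform(np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        cg.inverse_normal_transform(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# univariate AE


def test_pure_noise_gives_near_zero_h2():
    ped = _twin_pedigree(500, 500)
    rng = np.random.default_rng(5)
    fit = cg.fit_univariate_ae(rng.standard_normal(len(ped)), ped)
    assert fit.h2 < 0.05


def test_mz_duplicate_trait_drives_h2_to_one():
    ped = _twin_pedigree(200, 200)
    rng = np.random.default_rng(6)
    x = _simulate_trait(ped, 0.999, rng)
    fit = cg.fit_univariate_ae(x, ped)
    assert fit.h2 > 0.9


def test_h2_estimate_close_to_falconer():
    ped = _twin_pedigree(250, 250)
    rng = np.random.default_rng(7)
    x = _simulate_trait(ped, 0.5, rng)
    fit = cg.fit_univariate_ae(x, ped)
    mz = (ped.zygosity == "MZ").to_numpy()
    dz = (ped.zygosity == "DZ").to_numpy()
    r_mz = np.corrcoef(x[mz][0::2], x[mz][1::2])[0, 1]
    r_dz = np.corrcoef(x[dz][0::2], x[dz][1::2])[0, 1]
    falconer = 2 * (r_mz - r_dz)
    se = 2 * np.sqrt(2.0 / 250)
    assert abs(fit.h2 - 0.5) < 0.1
    assert abs(fit.h2 - falconer) < 2 * se


def test_h2_invariant_to_trait_rescaling_and_family_order():
    ped = _twin_pedigree(100, 100, 20)
    rng = np.random.default_rng(8)
    x = _simulate_trait(ped, 0.4, rng)
    base = cg.fit_univariate_ae(x, ped)
    scaled = cg.fit_univariate_ae(3.0 * x - 10.0, ped)
    assert scaled.h2 == pytest.approx(base.h2, abs=1e-6)
    perm = np.random.default_rng(9).permutation(len(ped))
    shuffled = cg.fit_univariate_ae(x[perm], ped.iloc[perm].reset_index(drop=True))
    assert shuffled.h2 == pytest.approx(base.h2, abs=1e-6)


def test_no_twin_pairs_rejected():
    ped = _twin_pedigree(0, 0, 30)
    with pytest.raises(ValueError, match="twin"):
        cg.fit_univariate_ae(np.random.default_rng(0).standard_normal(30), ped)


# ---------------------------------------------------------------------------
# bivariate AE


def test_identical_traits_give_unit_correlations():
    ped = _twin_pedigree(150, 150)
    rng = np.random.default_rng(10)
    x = _simulate_trait(ped, 0.5, rng)
    fit = cg.fit_bivariate_ae(x, x.copy(), ped, compute_pvalues=False)
    assert fit.rho_p > 0.99
    assert fit.rho_g > 0.99
    assert fit.rho_e > 0.99


def test_reconstruction_identity_holds_at_convergence():
    truth = cg.make_pair_ground_truth(0.5, 0.5, 0.6, 0.2)
    cohort = cg.simulate_cohort(truth, 150, 150, 0, seed=12)
    th = cohort.thickness.to_numpy()
    fit = cg.fit_bivariate_ae(th[:, 0], th[:, 1], cohort.pedigree, compute_pvalues=False)
    implied = fit.rho_g * np.sqrt(fit.h2_i * fit.h2_j) + fit.rho_e * np.sqrt(
        (1 - fit.h2_i) * (1 - fit.h2_j)
    )
    assert abs(implied - fit.rho_p) < 1e-6


def test_lrt_statistics_non_negative_and_restricted_ll_lower():
    truth = cg.make_pair_ground_truth(0.5, 0.5, 0.6, 0.2)
    cohort = cg.simulate_cohort(truth, 100, 100, 0, seed=13)
    th = cohort.thickness.to_numpy()
    ped = cohort.pedigree
    fit = cg.fit_bivariate_ae(th[:, 0], th[:, 1], ped, compute_pvalues=True)
    assert 0 <= fit.p_rho_g <= 1 and 0 <= fit.p_rho_e <= 1
    # strong planted rho_g must be detected
    assert fit.p_rho_g < 0.01


def test_lrt_null_p_values_not_degenerate():
    # independent traits: LRT p for rho_g should look uniform-ish
    ped = _twin_pedigree(80, 80)
    ps = []
    for s in range(40):
        rng = np.random.default_rng(1000 + s)
        x = _simulate_trait(ped, 0.5, rng)
        y = _simulate_trait(ped, 0.5, rng)
        fit = cg.fit_bivariate_ae(x, y, ped)
        ps.append(fit.p_rho_g)
    ps = np.asarray(ps)
    assert 0.0 < (ps < 0.5).mean() < 1.0  # spread across the unit interval
    assert (ps < 0.05).mean() < 0.25


# ---------------------------------------------------------------------------
# phenotypic decomposition


def test_decompose_fully_heritable_pair():
    g, e, prop = cg.decompose_phenotypic(1.0, 1.0, 0.5, 0.0)
    assert (g, e, prop) == (0.5, 0.0, 1.0)


def test_decompose_direct_arithmetic():
    g, e, prop = cg.decompose_phenotypic(0.5, 0.5, 0.6, 0.2)
    assert g == pytest.approx(0.3)
    assert e == pytest.approx(0.1)
    assert prop == pytest.approx(0.75)


def test_decompose_matches_bivariate_rho_p(rng):
    for _ in range(20):
        h2i, h2j = rng.uniform(0.05, 0.95, 2)
        rg, re = rng.uniform(-0.9, 0.9, 2)
        g, e, _ = cg.decompose_phenotypic(h2i, h2j, rg, re)
        expect = rg * np.sqrt(h2i * h2j) + re * np.sqrt((1 - h2i) * (1 - h2j))
        assert g + e == pytest.approx(expect, abs=1e-8)


def test_decompose_zero_rho_p_flagged():
    _, _, prop = cg.decompose_phenotypic(0.5, 0.5, 0.0, 0.0)
    assert np.isnan(prop)


# ---------------------------------------------------------------------------
# all-pairs matrix


def test_genetic_correlation_matrix_symmetric_unit_diagonal():
    geom = cg.make_sphere_parcellation(4, 2, seed=2)
    truth = cg.make_ground_truth(geom, cg.GroundTruthParams(h2_mean=0.5))
    cohort = cg.simulate_cohort(truth, 80, 80, 0, seed=14)
    resid = cg.residualize(cohort, ("age", "sex"))
    transformed = resid.apply(lambda c: cg.inverse_normal_transform(c.to_numpy()), axis=0)
    ae = cg.genetic_correlation_matrix(transformed, cohort.pedigree)
    assert np.allclose(ae.rho_g, ae.rho_g.T)
    assert np.allclose(np.diag(ae.rho_g), 1.0)
    assert np.allclose(np.diag(ae.rho_e), 1.0)
    assert ae.n_failed == 0
    assert np.all((ae.h2 >= 0) & (ae.h2 <= 1))
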