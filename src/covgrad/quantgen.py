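"""Twin-based AE (G + E) variance-component estimation.

Maximum-likelihood decomposition of parcel-wise phenotypes into additive
genetic (A) and unique environmental (E) components using MZ/DZ twin
pairs plus singletons.  The AE model implies, for a standardized trait,
a within-pair covariance of h2 (MZ) or h2/2 (DZ); for a pair of traits
the 4-variate pair covariance is parameterized by (h2_i, h2_j, rho_g,
rho_e), with the phenotypic correlation tied by the identity

    rho_p = rho_g * sqrt(h2_i * h2_j) + rho_e * sqrt((1-h2_i)(1-h2_j)).

Significance of rho_g / rho_e is assessed by likelihood-ratio tests
against restricted fits with the parameter pinned at zero (chi2 with one
degree of freedom).  Traits are expected residualized and inverse-normal
transformed upstream.

Implementation notes: the Gaussian pair likelihood depends on the data
only through per-zygosity second-moment matrices, so each function
evaluation costs O(1) in the number of families; the common scale is
profiled out analytically on standardized traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats

_H2_LO, _H2_HI = 1e-6, 1.0
_RHO_LIM = 0.9999


# ---------------------------------------------------------------------------
# inverse normal transform


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform.

    Maps ranks r (average ranks on ties) to Phi^{-1}((r - offset) /
    (n + 1 - 2*offset)); with the default Blom offset 3/8 this is
    (r - 3/8)/(n + 1/4).  Monotone in the input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.unique(x).size == 1:
        raise ValueError("all values equal; ranks undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size + 1 - 2 * offset))


# ---------------------------------------------------------------------------
# pedigree bookkeeping


@dataclass
class _PairedData:
    """Trait values arranged per zygosity group (pairs) and singletons."""

    mz: np.ndarray  # (n_mz, 2) or (n_mz, 4) for bivariate
    dz: np.ndarray
    singles: np.ndarray  # (n_s, 1) or (n_s, 2)


def _pair_indices(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-index pairs for MZ, DZ families and singleton rows."""
    ped = pedigree.reset_index(drop=True)
    out = {}
    for zyg in ("MZ", "DZ"):
        sub = ped[ped.zygosity == zyg]
        pairs = []
        for fam, grp in sub.groupby("family_id", sort=True):
            if len(grp) != 2:
                raise ValueError(f"{zyg} family {fam} does not have 2 members")
            pairs.append(grp.index.to_numpy())
        out[zyg] = np.array(pairs, dtype=int).reshape(-1, 2)
    singles = np.flatnonzero((ped.zygosity == "singleton").to_numpy())
    return out["MZ"], out["DZ"], singles


def _arrange(trait: np.ndarray, mz: np.ndarray, dz: np.ndarray, singles: np.ndarray) -> _PairedData:
    return _PairedData(
        mz=trait[mz] if len(mz) else np.empty((0, 2)),
        dz=trait[dz] if len(dz) else np.empty((0, 2)),
        singles=trait[singles][:, None] if len(singles) else np.empty((0, 1)),
    )


def _standardize_ml(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()  # ML (ddof=0)
    if sd == 0:
        raise ValueError("trait has zero variance")
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# univariate AE fit


@dataclass
class UnivariateAEFit:
    h2: float
    sigma_p2: float
    loglik: float
    converged: bool = True
    message: str = ""


def _uni_profile_loglik(h2: float, suff: dict) -> tuple[float, float]:
    """Profiled log-likelihood over (mean fixed 0, scale profiled).

    Returns (loglik, sigma_p2_hat).  ``suff`` holds per-group sufficient
    statistics of the standardized trait.
    """
    n_obs = suff["n_obs"]
    q = suff["S_s"]
    logdets = 0.0
    h2 = min(float(h2), 1.0 - 1e-10)  # keep MZ pair covariance invertible
    for key, r in (("mz", 1.0), ("dz", 0.5)):
        n_k = suff[f"n_{key}"]
        if n_k == 0:
            continue
        c = r * h2
        one_m = 1.0 - c * c
        q += (suff[f"S_{key}"] - 2.0 * c * suff[f"P_{key}"]) / one_m
        logdets += n_k * np.log(one_m)
    s2 = q / n_obs
    ll = -0.5 * (n_obs * np.log(2 * np.pi * s2) + logdets + n_obs)
    return ll, s2


def fit_univariate_ae(
    trait: np.ndarray, pedigree: pd.DataFrame, *, _pairs=None
) -> UnivariateAEFit:
    """ML fit of the AE twin model for one trait.

    Maximizes the Gaussian pair likelihood with within-pair covariance
    h2*sigma_p2 (MZ) and h2*sigma_p2/2 (DZ); h2 constrained to [0, 1];
    singletons contribute to the variance only.  The trait should be
    residualized / inverse-normal transformed upstream.
    """
    trait = np.asarray(trait, dtype=float)
    mz, dz, singles = _pairs if _pairs is not None else _pair_indices(pedigree)
    if len(mz) + len(dz) == 0:
        raise ValueError("no MZ or DZ twin pairs in pedigree")
    x = trait - trait.mean()
    scale = x.std()
    if scale == 0:
        raise ValueError("trait has zero variance")
    xs = x / scale
    data = _arrange(xs, mz, dz, singles)
    suff = dict(
        n_mz=len(data.mz),
        n_dz=len(data.dz),
        S_mz=float(np.sum(data.mz**2)),
        P_mz=float(np.sum(data.mz[:, 0] * data.mz[:, 1])),
        S_dz=float(np.sum(data.dz**2)),
        P_dz=float(np.sum(data.dz[:, 0] * data.dz[:, 1])),
        S_s=float(np.sum(data.singles**2)),
        n_obs=2 * len(data.mz) + 2 * len(data.dz) + len(data.singles),
    )
    grid = np.linspace(0.0, 1.0, 41)
    lls = np.array([_uni_profile_loglik(h, suff)[0] for h in grid])
    h0 = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda h: -_uni_profile_loglik(h, suff)[0],
        bounds=(max(0.0, h0 - 0.05), min(1.0, h0 + 0.05)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    h2 = float(res.x)
    ll, s2 = _uni_profile_loglik(h2, suff)
    return UnivariateAEFit(
        h2=h2,
        sigma_p2=float(s2 * scale**2),
        loglik=float(ll - suff["n_obs"] * np.log(scale)),
        converged=bool(res.success),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# bivariate AE fit


def _bivariate_moments(xi: np.ndarray, xj: np.ndarray, mz, dz, singles) -> dict:
    """Second-moment matrices per zygosity group for standardized traits.

    Pair vector order: (twin1_i, twin1_j, twin2_i, twin2_j).
    """
    out = {}
    for key, pairs in (("mz", mz), ("dz", dz)):
        if len(pairs) == 0:
            out[key] = (0, np.zeros((4, 4)))
            continue
        v = np.column_stack(
            [xi[pairs[:, 0]], xj[pairs[:, 0]], xi[pairs[:, 1]], xj[pairs[:, 1]]]
        )
        out[key] = (len(pairs), v.T @ v)
    if len(singles):
        v = np.column_stack([xi[singles], xj[singles]])
        out["s"] = (len(singles), v.T @ v)
    else:
        out["s"] = (0, np.zeros((2, 2)))
    out["n_obs"] = 4 * out["mz"][0] + 4 * out["dz"][0] + 2 * out["s"][0]
    return out


def _pair_correlation_matrix(h2i, h2j, rho_g, rho_e, r_k) -> np.ndarray:
    g = rho_g * np.sqrt(h2i * h2j)
    e = rho_e * np.sqrt((1.0 - h2i) * (1.0 - h2j))
    rp = g + e
    w = np.array([[1.0, rp], [rp, 1.0]])
    b = r_k * np.array([[h2i, g], [g, h2j]])
    return np.block([[w, b], [b, w]])


def _biv_nll(theta: np.ndarray, moments: dict, fixed: dict) -> float:
    """Negative profiled log-likelihood; scale profiled analytically."""
    params = dict(fixed)
    names = [n for n in ("h2i", "h2j", "rho_g", "rho_e") if n not in fixed]
    params.update(zip(names, theta))
    h2i, h2j = params["h2i"], params["h2j"]
    rho_g, rho_e = params["rho_g"], params["rho_e"]
    rp = rho_g * np.sqrt(h2i * h2j) + rho_e * np.sqrt((1 - h2i) * (1 - h2j))
    if abs(rp) >= _RHO_LIM:
        return 1e10
    q = 0.0
    logdets = 0.0
    for key, r_k in (("mz", 1.0), ("dz", 0.5)):
        n_k, m = moments[key]
        if n_k == 0:
            continue
        c = _pair_correlation_matrix(h2i, h2j, rho_g, rho_e, r_k)
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            return 1e10
        q += float(np.trace(np.linalg.solve(c, m)))
        logdets += n_k * logdet
    n_s, m_s = moments["s"]
    if n_s:
        c = np.array([[1.0, rp], [rp, 1.0]])
        sign, logdet = np.linalg.slogdet(c)
        if sign <= 0:
            return 1e10
        q += float(np.trace(np.linalg.solve(c, m_s)))
        logdets += n_s * logdet
    n_obs = moments["n_obs"]
    if q <= 0:
        return 1e10
    s2 = q / n_obs
    return 0.5 * (n_obs * np.log(2 * np.pi * s2) + logdets + n_obs)


def _optimize_biv(moments: dict, fixed: dict, starts: list[dict]) -> tuple[dict, float]:
    names = [n for n in ("h2i", "h2j", "rho_g", "rho_e") if n not in fixed]
    bounds = []
    for n in names:
        bounds.append((_H2_LO, 1 - _H2_LO) if n.startswith("h2") else (-_RHO_LIM, _RHO_LIM))
    best, best_nll = None, np.inf
    for start in starts:
        x0 = np.array([np.clip(start[n], b[0] + 1e-4, b[1] - 1e-4) for n, b in zip(names, bounds)])
        res = optimize.minimize(
            _biv_nll,
            x0,
            args=(moments, fixed),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best = dict(fixed)
            best.update(zip(names, res.x))
    return best, -best_nll


@dataclass
class BivariateAEFit:
    h2_i: float
    h2_j: float
    rho_g: float
    rho_e: float
    rho_p: float
    loglik: float
    p_rho_g: float | None = None
    p_rho_e: float | None = None
    flags: list[str] = field(default_factory=list)


def _moment_starts(moments: dict, h2i0: float, h2j0: float) -> list[dict]:
    """Heuristic starts from empirical within-person and cross-twin moments."""
    n_mz, m_mz = moments["mz"]
    n_dz, m_dz = moments["dz"]
    n_s, m_s = moments["s"]
    # within-person cross-trait correlation (phenotypic)
    num = den_i = den_j = 0.0
    for n_k, m in ((n_mz, m_mz), (n_dz, m_dz)):
        if n_k:
            num += m[0, 1] + m[2, 3]
            den_i += m[0, 0] + m[2, 2]
            den_j += m[1, 1] + m[3, 3]
    if n_s:
        num += m_s[0, 1]
        den_i += m_s[0, 0]
        den_j += m_s[1, 1]
    rp0 = float(np.clip(num / np.sqrt(max(den_i * den_j, 1e-12)), -0.95, 0.95))
    # MZ cross-twin cross-trait covariance estimates rho_g*sqrt(h2i*h2j)
    if n_mz:
        cg = float((m_mz[0, 3] + m_mz[1, 2]) / (2 * n_mz))
    elif n_dz:
        cg = 2.0 * float((m_dz[0, 3] + m_dz[1, 2]) / (2 * n_dz))
    else:
        cg = 0.0
    denom = np.sqrt(max(h2i0 * h2j0, 1e-6))
    rg0 = float(np.clip(cg / denom, -0.95, 0.95))
    edenom = np.sqrt(max((1 - h2i0) * (1 - h2j0), 1e-6))
    re0 = float(np.clip((rp0 - rg0 * denom) / edenom, -0.95, 0.95))
    return [
        dict(h2i=h2i0, h2j=h2j0, rho_g=rg0, rho_e=re0),
        dict(h2i=0.5, h2j=0.5, rho_g=rp0, rho_e=rp0),
    ]


def fit_bivariate_ae(
    trait_i: np.ndarray,
    trait_j: np.ndarray,
    pedigree: pd.DataFrame,
    *,
    compute_pvalues: bool = True,
    _pairs=None,
) -> BivariateAEFit:
    """ML fit of the bivariate AE twin model for a trait pair.

    Maximizes the 4-variate Gaussian pair likelihood over (h2_i, h2_j,
    rho_g, rho_e) with the common scale profiled out; likelihood-ratio
    p-values come from restricted fits with rho_g = 0 or rho_e = 0
    (chi-squared, 1 df).
    """
    mz, dz, singles = _pairs if _pairs is not None else _pair_indices(pedigree)
    if len(mz) + len(dz) == 0:
        raise ValueError("no MZ or DZ twin pairs in pedigree")
    xi = _standardize_ml(np.asarray(trait_i, dtype=float))
    xj = _standardize_ml(np.asarray(trait_j, dtype=float))
    moments = _bivariate_moments(xi, xj, mz, dz, singles)
    h2i0 = fit_univariate_ae(xi, pedigree, _pairs=(mz, dz, singles)).h2
    h2j0 = fit_univariate_ae(xj, pedigree, _pairs=(mz, dz, singles)).h2
    starts = _moment_starts(moments, np.clip(h2i0, 0.05, 0.95), np.clip(h2j0, 0.05, 0.95))
    best, ll_full = _optimize_biv(moments, {}, starts)
    flags = []
    if min(best["h2i"], best["h2j"]) < 1e-3:
        flags.append("h2_boundary:rho_g_poorly_identified")
    rho_p = best["rho_g"] * np.sqrt(best["h2i"] * best["h2j"]) + best["rho_e"] * np.sqrt(
        (1 - best["h2i"]) * (1 - best["h2j"])
    )
    p_g = p_e = None
    if compute_pvalues:
        _, ll_g0 = _optimize_biv(moments, {"rho_g": 0.0}, starts)
        _, ll_e0 = _optimize_biv(moments, {"rho_e": 0.0}, starts)
        lrt_g = max(0.0, 2.0 * (ll_full - ll_g0))
        lrt_e = max(0.0, 2.0 * (ll_full - ll_e0))
        p_g = float(stats.chi2.sf(lrt_g, 1))
        p_e = float(stats.chi2.sf(lrt_e, 1))
        if abs(best["rho_g"]) > _RHO_LIM - 1e-3 or abs(best["rho_e"]) > _RHO_LIM - 1e-3:
            flags.append("rho_boundary:lrt_approximate")
    return BivariateAEFit(
        h2_i=float(best["h2i"]),
        h2_j=float(best["h2j"]),
        rho_g=float(best["rho_g"]),
        rho_e=float(best["rho_e"]),
        rho_p=float(rho_p),
        loglik=float(ll_full),
        p_rho_g=p_g,
        p_rho_e=p_e,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# decomposition of the phenotypic correlation


def decompose_phenotypic(
    h2_i: float, h2_j: float, rho_g: float, rho_e: float
) -> tuple[float, float, float]:
    """Split a phenotypic correlation into genetic and environmental paths.

    rho_ph_g = sqrt(h2_i)*rho_g*sqrt(h2_j); rho_ph_e analogous with
    (1 - h2); prop_genetic = rho_ph_g / (rho_ph_g + rho_ph_e) = rho_ph_g /
    rho_p.  Returns (rho_ph_g, rho_ph_e, prop_genetic); prop_genetic is
    NaN when rho_p = 0.
    """
    for h in (h2_i, h2_j):
        if not 0 <= h <= 1:
            raise ValueError("h2 must be in [0, 1]")
    for r in (rho_g, rho_e):
        if not -1 <= r <= 1:
            raise ValueError("correlations must be in [-1, 1]")
    rho_ph_g = np.sqrt(h2_i) * rho_g * np.sqrt(h2_j)
    rho_ph_e = np.sqrt(1 - h2_i) * rho_e * np.sqrt(1 - h2_j)
    rho_p = rho_ph_g + rho_ph_e
    prop = rho_ph_g / rho_p if rho_p != 0 else float("nan")
    return float(rho_ph_g), float(rho_ph_e), float(prop)


# ---------------------------------------------------------------------------
# all-pairs genetic correlation matrix


@dataclass
class AEFit:
    """All-pairs AE decomposition over a parcel set."""

    parcel_ids: np.ndarray
    h2: np.ndarray
    rho_g: np.ndarray
    rho_e: np.ndarray
    rho_p: np.ndarray
    loglik: np.ndarray
    p_rho_g: np.ndarray | None
    p_rho_e: np.ndarray | None
    prop_genetic: np.ndarray
    n_failed: int = 0


def genetic_correlation_matrix(
    phenotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    *,
    compute_pvalues: bool = False,
) -> AEFit:
    """Bivariate AE fits over all parcel pairs.

    ``phenotypes`` is subjects x parcels, already residualized and
    inverse-normal transformed, rows aligned with ``pedigree``.  Per-pair
    failures are recorded and the matrix cell left missing.
    """
    parcel_ids = np.asarray(phenotypes.columns)
    x = phenotypes.to_numpy(float)
    p = x.shape[1]
    pairs_idx = _pair_indices(pedigree)
    h2 = np.empty(p)
    for j in range(p):
        h2[j] = fit_univariate_ae(x[:, j], pedigree, _pairs=pairs_idx).h2
    rho_g = np.eye(p)
    rho_e = np.eye(p)
    rho_p = np.eye(p)
    loglik = np.zeros((p, p))
    pg = np.full((p, p), np.nan) if compute_pvalues else None
    pe = np.full((p, p), np.nan) if compute_pvalues else None
    prop = np.full((p, p), np.nan)
    n_failed = 0
    for i, j in combinations(range(p), 2):
        try:
            fit = fit_bivariate_ae(
                x[:, i], x[:, j], pedigree, compute_pvalues=compute_pvalues, _pairs=pairs_idx
            )
        except Exception:
            n_failed += 1
            rho_g[i, j] = rho_g[j, i] = np.nan
            rho_e[i, j] = rho_e[j, i] = np.nan
            rho_p[i, j] = rho_p[j, i] = np.nan
            continue
        rho_g[i, j] = rho_g[j, i] = fit.rho_g
        rho_e[i, j] = rho_e[j, i] = fit.rho_e
        rho_p[i, j] = rho_p[j, i] = fit.rho_p
        loglik[i, j] = loglik[j, i] = fit.loglik
        if compute_pvalues:
            pg[i, j] = pg[j, i] = fit.p_rho_g
            pe[i, j] = pe[j, i] = fit.p_rho_e
        g_path, e_path, pr = decompose_phenotypic(fit.h2_i, fit.h2_j, fit.rho_g, fit.rho_e)
        prop[i, j] = prop[j, i] = pr
    return AEFit(
        parcel_ids=parcel_ids,
        h2=h2,
        rho_g=rho_g,
        rho_e=rho_e,
        rho_p=rho_p,
        loglik=loglik,
        p_rho_g=pg,
        p_rho_e=pe,
        prop_genetic=prop,
        n_failed=n_failed,
    )
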