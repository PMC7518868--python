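"""Structural covariance: aggregation, residualization, correlation, and
community-level summaries with a permutation null.

Structural covariance is the interregional Pearson correlation of a
morphological measure (here parcel-mean cortical thickness) across
subjects, computed on residuals after removing nuisance covariates
(age, sex, global thickness; optionally age², age×sex and site).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .geometry import ParcelGeometry
from .matrices import SymmetricParcelMatrix
from .simulate import TwinCohort

#: covariate presets; "covariance" follows the structural-covariance
#: analysis, "genetic" the variance-component analysis (adds age² and
#: age×sex).  "global" is the per-subject mean parcel thickness.
COVARIATE_PRESETS = {
    "covariance": ("age", "sex", "global"),
    "genetic": ("age", "sex", "age2", "agexsex", "global"),
}

_TERMS = ("age", "sex", "age2", "agexsex", "global", "site")


def aggregate_parcels(
    vertex_values: np.ndarray, geom: ParcelGeometry, trim_fraction: float = 0.10
) -> np.ndarray:
    """Trimmed-mean aggregation of per-vertex values to parcels.

    Per parcel with m vertices, drops floor(trim_fraction*m) smallest and
    largest values and averages the rest; medial-wall vertices ignored.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    vertex_values = np.asarray(vertex_values, dtype=float)
    out = np.empty(geom.n_parcels)
    for p in range(geom.n_parcels):
        vals = vertex_values[geom.vertex_to_parcel == p]
        if vals.size == 0:
            raise ValueError(f"parcel {p} has no vertices")
        cut = int(np.floor(trim_fraction * vals.size))
        vals = np.sort(vals, kind="stable")
        out[p] = vals[cut : vals.size - cut].mean()
    return out


def design_matrix(
    pedigree: pd.DataFrame, terms: tuple[str, ...], global_thickness: np.ndarray | None
) -> tuple[np.ndarray, list[str]]:
    """Intercept + requested covariate columns."""
    cols = [np.ones(len(pedigree))]
    names = ["intercept"]
    age = pedigree.age.to_numpy(float)
    sex = pedigree.sex.to_numpy(float)
    for t in terms:
        if t == "age":
            cols.append(age)
        elif t == "sex":
            cols.append(sex)
        elif t == "age2":
            cols.append(age**2)
        elif t == "agexsex":
            cols.append(age * sex)
        elif t == "global":
            if global_thickness is None:
                raise ValueError("global thickness required by covariate spec")
            cols.append(global_thickness)
        elif t == "site":
            site = pedigree.site.to_numpy()
            levels = np.unique(site)
            for lev in levels[1:]:  # first level absorbed by intercept
                cols.append((site == lev).astype(float))
                names.append(f"site_{lev}")
            continue
        else:
            raise ValueError(f"unknown covariate term {t!r}; known: {_TERMS}")
        names.append(t)
    return np.column_stack(cols), names


def residualize(
    cohort: TwinCohort, covariate_spec: tuple[str, ...] | str = "covariance"
) -> pd.DataFrame:
    """OLS residuals of every parcel against the covariate design.

    ``covariate_spec`` is a preset name or an explicit tuple of terms from
    {age, sex, age2, agexsex, global, site}.  Global thickness is the
    per-subject mean over parcels.
    """
    if isinstance(covariate_spec, str):
        covariate_spec = COVARIATE_PRESETS[covariate_spec]
    y = cohort.thickness.to_numpy(float)
    global_th = y.mean(axis=1)
    x, names = design_matrix(cohort.pedigree, tuple(covariate_spec), global_th)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify collinear columns by pivoted QR diagnostics
        _, r = np.linalg.qr(x)
        small = np.abs(np.diag(r)) < 1e-10 * np.abs(np.diag(r)).max()
        bad = [names[i] for i in np.flatnonzero(small)]
        raise ValueError(f"design matrix rank deficient; collinear terms: {bad}")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid, index=cohort.thickness.index, columns=cohort.thickness.columns)


def structural_covariance(residuals: pd.DataFrame | np.ndarray) -> SymmetricParcelMatrix:
    """Parcel-pair Pearson correlation across subjects (unit diagonal)."""
    if isinstance(residuals, pd.DataFrame):
        parcel_ids = np.asarray(residuals.columns)
        r = residuals.to_numpy(float)
    else:
        r = np.asarray(residuals, dtype=float)
        parcel_ids = np.arange(r.shape[1])
    n, p = r.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = r.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(f"zero-variance parcels: {parcel_ids[zero].tolist()}")
    c = np.corrcoef(r, rowvar=False)
    np.fill_diagonal(c, 1.0)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    return SymmetricParcelMatrix(
        values=c,
        kind="covariance",
        parcel_ids=parcel_ids,
        meta={"n_subjects": n},
    )


@dataclass
class CommunitySummary:
    within_mean: float
    between_mean: float
    per_community: dict  # community -> dict(mean=..., p_value=..., q_value=...)


def community_test(
    mat: SymmetricParcelMatrix,
    communities: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> CommunitySummary:
    """Within- vs between-community covariance with a label-permutation null.

    The null preserves community sizes by permuting parcel labels; the
    one-sided p-value per community is (1 + #{null >= observed}) /
    (n_perm + 1); q-values by Benjamini-Hochberg.
    """
    communities = np.asarray(communities)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels, counts = np.unique(communities, return_counts=True)
    keep = labels[counts >= 2]
    if len(keep) < 2:
        raise ValueError("need at least 2 communities with >= 2 parcels")
    dropped = set(labels) - set(keep)
    if dropped:
        warnings.warn(f"communities with < 2 parcels excluded: {sorted(dropped)}")
    v = mat.values
    p = mat.n_parcels
    off = ~np.eye(p, dtype=bool)
    same = communities[:, None] == communities[None, :]
    within_mean = float(v[same & off].mean())
    between_mean = float(v[~same].mean())

    rng = np.random.default_rng(seed)
    observed = {}
    null = np.empty((n_perm, len(keep)))
    masks = {c: communities == c for c in keep}
    for j, c in enumerate(keep):
        m = masks[c]
        block = v[np.ix_(m, m)]
        observed[c] = float(block[~np.eye(m.sum(), dtype=bool)].mean())
    for i in range(n_perm):
        perm = rng.permutation(p)
        for j, c in enumerate(keep):
            idx = perm[masks[c]]
            block = v[np.ix_(idx, idx)]
            null[i, j] = block[~np.eye(len(idx), dtype=bool)].mean()
    pvals = np.array(
        [(1 + np.sum(null[:, j] >= observed[c])) / (n_perm + 1) for j, c in enumerate(keep)]
    )
    _, qvals, _, _ = multipletests(pvals, alpha=fdr_alpha, method="fdr_bh")
    per_community = {
        int(c): dict(mean=observed[c], p_value=float(pvals[j]), q_value=float(qvals[j]))
        for j, c in enumerate(keep)
    }
    return CommunitySummary(
        within_mean=within_mean, between_mean=between_mean, per_community=per_community
    )


def qc_hemispheric_difference(
    cohort: TwinCohort, geom: ParcelGeometry, threshold_cm: float = 0.2
) -> list[str]:
    """Subjects whose |mean L - mean R| thickness exceeds the threshold are
    excluded; returns retained subject ids.  Threshold in cm, thickness mm."""
    left = geom.hemisphere_mask("L")
    right = geom.hemisphere_mask("R")
    if not (left.any() and right.any()):
        raise ValueError("both hemispheres must be present")
    th = cohort.thickness.to_numpy(float)
    diff_mm = np.abs(th[:, left].mean(axis=1) - th[:, right].mean(axis=1))
    keep = diff_mm <= threshold_cm * 10.0
    return list(cohort.pedigree.subject_id[keep])
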