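"""Synthetic twin cohorts with planted genetic/environmental covariance.

The generator emulates the essential statistical features of a young-adult
twin imaging cohort: monozygotic (MZ) and dizygotic (DZ) twin pairs plus
unrelated singletons, parcel-wise cortical thickness whose additive-genetic
and unique-environmental covariance both carry smooth low-dimensional
spatial structure (two orthogonal planted axes on the sphere), and linear
covariate effects (age, sex, site intercepts).

The additive-genetic model is the classical twin expectation: MZ co-twins
share their additive values exactly, DZ co-twins share them with
correlation 1/2 (a2 = a1/2 + (sqrt(3)/2)·a_indep), environmental deviates
are independent per subject.  Everything downstream — heritability,
genetic correlation, gradient recovery — can therefore be checked against
the stored :class:`GroundTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import ParcelGeometry

_PSD_JITTER = 1e-8


@dataclass
class TwinCohort:
    """Subjects with family structure, covariates and parcel thickness.

    ``pedigree`` columns: subject_id, family_id, zygosity (MZ/DZ/singleton),
    age (years), sex (0/1), site (int).  ``thickness`` is a subjects x
    parcels DataFrame (mm), row-indexed by subject_id.
    """

    pedigree: pd.DataFrame
    thickness: pd.DataFrame

    def __post_init__(self) -> None:
        ped = self.pedigree
        required = {"subject_id", "family_id", "zygosity", "age", "sex", "site"}
        missing = required - set(ped.columns)
        if missing:
            raise ValueError(f"pedigree missing columns: {sorted(missing)}")
        if ped[list(required)].isna().any().any():
            raise ValueError("pedigree has missing values")
        sizes = ped[ped.zygosity.isin(["MZ", "DZ"])].groupby("family_id").size()
        bad = sizes[sizes != 2]
        if len(bad):
            raise ValueError(f"MZ/DZ families must have exactly 2 members: {bad.index.tolist()}")
        th = self.thickness.to_numpy()
        if not np.all(np.isfinite(th)) or np.any(th <= 0):
            raise ValueError("thickness must be finite and positive")
        if not ped.subject_id.is_unique:
            raise ValueError("duplicate subject ids")
        if list(self.thickness.index) != list(ped.subject_id):
            raise ValueError("thickness rows must align with pedigree subject order")

    @property
    def n_subjects(self) -> int:
        return len(self.pedigree)

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.asarray([int(c) for c in self.thickness.columns])


@dataclass
class GroundTruthParams:
    """Generator settings for the planted covariance structure.

    h2_mean : planted per-parcel heritability (constant across parcels).
    w1, w2 : weights of the two planted gradient kernels in sigma_g.
    length_scale : squared-exponential length scale on the standardized
        planted axes (axis units; axes have SD 1).
    unique_variance : parcel-unique (white) variance weight in each kernel
        mixture; keeps the correlation matrices full rank.
    e_w1, e_w2, e_length_scale : analogous settings for sigma_e.
    pheno_sd : total phenotypic SD per parcel in mm.
    baseline_mm : grand-mean cortical thickness.
    """

    h2_mean: float = 0.5
    w1: float = 1.0
    w2: float = 0.5
    length_scale: float = 0.5
    unique_variance: float = 0.3
    e_w1: float = 0.4
    e_w2: float = 0.4
    e_length_scale: float = 0.8
    pheno_sd: float = 0.15
    baseline_mm: float = 2.5


@dataclass
class GroundTruth:
    """Planted covariance structure with analytic summaries."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray
    h2_true: np.ndarray
    rho_g_true: np.ndarray
    rho_e_true: np.ndarray
    g1_axis: np.ndarray
    g2_axis: np.ndarray
    betas: dict = field(default_factory=dict)
    params: GroundTruthParams = field(default_factory=GroundTruthParams)
    geometry: ParcelGeometry | None = None


def _sq_exp_kernel(axis: np.ndarray, length_scale: float) -> np.ndarray:
    d = axis[:, None] - axis[None, :]
    return np.exp(-0.5 * (d / length_scale) ** 2)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _correlation_mixture(
    g1: np.ndarray, g2: np.ndarray, w1: float, w2: float, unique: float, ell: float
) -> np.ndarray:
    p = len(g1)
    total = w1 + w2 + unique
    if total <= 0:
        raise ValueError("kernel mixture weights must be positive in total")
    mix = unique * np.eye(p)
    if w1 > 0:
        mix += w1 * _sq_exp_kernel(g1, ell)
    if w2 > 0:
        mix += w2 * _sq_exp_kernel(g2, ell)
    return mix / total


def make_ground_truth(
    geom: ParcelGeometry, params: GroundTruthParams | None = None
) -> GroundTruth:
    """Plant two orthogonal spatial axes into genetic/environmental covariance.

    The axes are the y (posterior-anterior) and z (inferior-superior)
    spherical coordinates of the parcel centroids, standardized.  Genetic
    and environmental covariance are squared-exponential kernel mixtures
    over these axes plus a parcel-unique term, normalized to correlation
    form and scaled so every parcel has heritability ``h2_mean``.
    """
    params = params or GroundTruthParams()
    if not 0 < params.h2_mean < 1:
        raise ValueError("h2_mean must be in (0, 1)")
    if params.length_scale <= 0 or params.e_length_scale <= 0:
        raise ValueError("length scales must be positive")
    g1 = _standardize(geom.centroids[:, 1])
    g2 = _standardize(geom.centroids[:, 2])
    c_g = _correlation_mixture(
        g1, g2, params.w1, params.w2, params.unique_variance, params.length_scale
    )
    c_e = _correlation_mixture(
        g1, g2, params.e_w1, params.e_w2, params.unique_variance, params.e_length_scale
    )
    var = params.pheno_sd**2
    sigma_g = params.h2_mean * var * c_g
    sigma_e = (1.0 - params.h2_mean) * var * c_e
    for name, m in (("sigma_g", sigma_g), ("sigma_e", sigma_e)):
        try:
            np.linalg.cholesky(m + _PSD_JITTER * var * np.eye(len(m)))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - by construction PSD
            raise ValueError(f"{name} is not positive semi-definite") from exc
    p = geom.n_parcels
    h2_true = np.full(p, params.h2_mean)
    # spatially varying covariate slopes (mm/yr, mm)
    betas = {
        "age": -0.002 * (1.0 + 0.3 * g1),
        "sex": 0.02 * (1.0 + 0.3 * g2),
        "site": 0.01,
    }
    return GroundTruth(
        sigma_g=sigma_g,
        sigma_e=sigma_e,
        h2_true=h2_true,
        rho_g_true=c_g,
        rho_e_true=c_e,
        g1_axis=g1,
        g2_axis=g2,
        betas=betas,
        params=params,
        geometry=geom,
    )


def make_pair_ground_truth(
    h2_i: float = 0.5,
    h2_j: float = 0.5,
    rho_g: float = 0.6,
    rho_e: float = 0.2,
    pheno_sd: float = 0.15,
) -> GroundTruth:
    """Two-parcel ground truth with exact planted (h2, rho_g, rho_e).

    Convenience constructor for parameter-recovery studies where the
    bivariate AE parameters must be planted directly rather than via the
    spatial kernels.
    """
    params = GroundTruthParams(h2_mean=(h2_i + h2_j) / 2.0, pheno_sd=pheno_sd)
    var = pheno_sd**2
    sg = var * np.array(
        [[h2_i, rho_g * np.sqrt(h2_i * h2_j)], [rho_g * np.sqrt(h2_i * h2_j), h2_j]]
    )
    se = var * np.array(
        [
            [1 - h2_i, rho_e * np.sqrt((1 - h2_i) * (1 - h2_j))],
            [rho_e * np.sqrt((1 - h2_i) * (1 - h2_j)), 1 - h2_j],
        ]
    )
    return GroundTruth(
        sigma_g=sg,
        sigma_e=se,
        h2_true=np.array([h2_i, h2_j]),
        rho_g_true=np.array([[1.0, rho_g], [rho_g, 1.0]]),
        rho_e_true=np.array([[1.0, rho_e], [rho_e, 1.0]]),
        g1_axis=np.array([0.0, 1.0]),
        g2_axis=np.array([0.0, 0.0]),
        betas={"age": np.zeros(2), "sex": np.zeros(2), "site": 0.0},
        params=params,
    )


@dataclass
class CovariateModel:
    """Covariate distributions: age ~ U(age_min, age_max) shared within a
    twin pair, sex ~ Bernoulli(0.5) per subject (shared for MZ), site
    uniform over ``n_sites`` labels shared within family."""

    age_min: float = 22.0
    age_max: float = 37.0
    n_sites: int = 1


def simulate_cohort(
    truth: GroundTruth,
    n_mz: int,
    n_dz: int,
    n_singleton: int = 0,
    covariate_model: CovariateModel | None = None,
    seed: int = 0,
) -> TwinCohort:
    """Draw a twin cohort from the planted covariance structure.

    Per family, additive values a ~ MVN(0, sigma_g) with cross-twin genetic
    correlation 1 (MZ) or 1/2 (DZ); environmental deviates e ~ MVN(0,
    sigma_e) independent per subject; thickness = baseline + X·beta + a + e.
    Deterministic for fixed seed.
    """
    if min(n_mz, n_dz, n_singleton) < 0:
        raise ValueError("counts must be non-negative")
    n_subjects = 2 * (n_mz + n_dz) + n_singleton
    if n_subjects == 0:
        raise ValueError("cohort would be empty")
    cm = covariate_model or CovariateModel()
    rng = np.random.default_rng(seed)
    p = truth.sigma_g.shape[0]
    jit = _PSD_JITTER * truth.params.pheno_sd**2 * np.eye(p)
    chol_g = np.linalg.cholesky(truth.sigma_g + jit)
    chol_e = np.linalg.cholesky(truth.sigma_e + jit)

    rows = []
    thick = np.empty((n_subjects, p))
    idx = 0
    fam = 0

    def draw_g(n: int) -> np.ndarray:
        return rng.standard_normal((n, p)) @ chol_g.T

    def draw_e(n: int) -> np.ndarray:
        return rng.standard_normal((n, p)) @ chol_e.T

    def covariate_effect(age: float, sex: int, site: int) -> np.ndarray:
        eff = truth.betas["age"] * (age - 0.5 * (cm.age_min + cm.age_max))
        eff = eff + truth.betas["sex"] * sex
        eff = eff + truth.betas["site"] * site
        return eff

    for zyg, n_fam in (("MZ", n_mz), ("DZ", n_dz)):
        for _ in range(n_fam):
            a1 = draw_g(1)[0]
            if zyg == "MZ":
                a2 = a1
            else:
                a2 = 0.5 * a1 + (np.sqrt(3.0) / 2.0) * draw_g(1)[0]
            e = draw_e(2)
            age = rng.uniform(cm.age_min, cm.age_max)
            site = int(rng.integers(cm.n_sites))
            if zyg == "MZ":
                sexes = [int(rng.integers(2))] * 2
            else:
                sexes = [int(rng.integers(2)), int(rng.integers(2))]
            for k, a in enumerate((a1, a2)):
                rows.append(
                    dict(
                        subject_id=f"S{idx:05d}",
                        family_id=f"F{fam:05d}",
                        zygosity=zyg,
                        age=age,
                        sex=sexes[k],
                        site=site,
                    )
                )
                thick[idx] = (
                    truth.params.baseline_mm
                    + covariate_effect(age, sexes[k], site)
                    + a
                    + e[k]
                )
                idx += 1
            fam += 1
    for _ in range(n_singleton):
        a = draw_g(1)[0]
        e = draw_e(1)[0]
        age = rng.uniform(cm.age_min, cm.age_max)
        sex = int(rng.integers(2))
        site = int(rng.integers(cm.n_sites))
        rows.append(
            dict(
                subject_id=f"S{idx:05d}",
                family_id=f"F{fam:05d}",
                zygosity="singleton",
                age=age,
                sex=sex,
                site=site,
            )
        )
        thick[idx] = truth.params.baseline_mm + covariate_effect(age, sex, site) + a + e
        idx += 1
        fam += 1

    pedigree = pd.DataFrame(rows)
    thickness = pd.DataFrame(
        thick, index=pedigree.subject_id, columns=[str(j) for j in range(p)]
    )
    return TwinCohort(pedigree=pedigree, thickness=thickness)
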