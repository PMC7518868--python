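"""End-to-end pipeline: simulate -> covariance -> variance components ->
gradients -> spatial statistics -> report.

A single YAML-configurable entry point that runs the enabled stages in
dependency order on a synthetic cohort, writes every artifact with a
JSON sidecar (settings, seed), and logs all derived seeds.  The master
seed fans out to per-stage child seeds through ``numpy.random
.SeedSequence.spawn`` so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import covariance as cov
from . import gradients as grad
from . import quantgen as qg
from . import spatial
from .geometry import make_sphere_parcellation
from .io import write_cohort, write_geometry, write_ground_truth, write_matrix
from .matrices import SymmetricParcelMatrix
from .simulate import CovariateModel, GroundTruthParams, make_ground_truth, simulate_cohort

log = logging.getLogger("covgrad")

_STAGES = ("simulate", "covariance", "quantgen", "gradients", "spatial")


@dataclass
class PipelineConfig:
    """Validated settings for a full synthetic run."""

    seed: int = 0
    out_dir: str = "covgrad_run"
    stages: tuple[str, ...] = _STAGES
    # simulation
    n_parcels: int = 100
    mesh_resolution: int = 4
    n_mz: int = 200
    n_dz: int = 200
    n_singleton: int = 50
    h2_mean: float = 0.5
    w1: float = 1.0
    w2: float = 0.5
    length_scale: float = 0.5
    unique_variance: float = 0.3
    # covariance
    trim_fraction: float = 0.10
    covariate_preset: str = "covariance"
    qc_threshold_cm: float = 0.2
    n_perm: int = 1000
    # quantgen
    quantgen_max_parcels: int = 20
    # gradients
    keep_fraction: float = 0.10
    alpha: float = 0.5
    n_components: int = 10
    n_bins: int = 10
    # spatial
    n_rotations: int = 1000

    def validate(self) -> None:
        checks = [
            (self.n_parcels >= 4, "n_parcels must be >= 4"),
            (0 < self.keep_fraction <= 1, "keep_fraction must be in (0, 1]"),
            (0 <= self.trim_fraction < 0.5, "trim_fraction must be in [0, 0.5)"),
            (0 < self.h2_mean < 1, "h2_mean must be in (0, 1)"),
            (self.n_components >= 1, "n_components must be >= 1"),
            (self.n_perm >= 100, "n_perm must be >= 100"),
            (self.n_rotations >= 10, "n_rotations must be >= 10"),
            (self.n_mz + self.n_dz >= 1, "need at least one twin family"),
            (self.covariate_preset in cov.COVARIATE_PRESETS, "unknown covariate preset"),
            (set(self.stages) <= set(_STAGES), f"stages must be among {_STAGES}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    """Per-stage child seeds (< 2**31) from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _sidecar(path: Path, **info) -> None:
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(info, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    seeds = dict(zip(_STAGES, _child_seeds(config.seed, len(_STAGES))))
    log.info("stage seeds: %s", seeds)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2, default=list))
    (out / "seeds.json").write_text(json.dumps(seeds, indent=2))
    report: dict = {"seeds": seeds}

    geom = make_sphere_parcellation(
        config.n_parcels, config.mesh_resolution, seed=seeds["simulate"]
    )
    truth = make_ground_truth(
        geom,
        GroundTruthParams(
            h2_mean=config.h2_mean,
            w1=config.w1,
            w2=config.w2,
            length_scale=config.length_scale,
            unique_variance=config.unique_variance,
        ),
    )
    cohort = simulate_cohort(
        truth, config.n_mz, config.n_dz, config.n_singleton,
        CovariateModel(), seed=seeds["simulate"],
    )
    if "simulate" in config.stages:
        write_cohort(cohort, out / "phenotypes.tsv", out / "pedigree.csv")
        write_geometry(geom, out / "geometry")
        write_ground_truth(truth, out / "ground_truth.npz")
        _sidecar(out / "phenotypes.tsv", stage="simulate", seed=seeds["simulate"])

    matrix = None
    if "covariance" in config.stages:
        retained = cov.qc_hemispheric_difference(cohort, geom, config.qc_threshold_cm)
        report["qc_retained"] = len(retained)
        resid = cov.residualize(cohort, config.covariate_preset)
        matrix = cov.structural_covariance(resid)
        write_matrix(matrix, out / "structural_covariance.tsv")
        summary = cov.community_test(
            matrix, geom.community, n_perm=config.n_perm, seed=seeds["covariance"]
        )
        report["community"] = {
            "within_mean": summary.within_mean,
            "between_mean": summary.between_mean,
            "per_community": summary.per_community,
        }

    ae = None
    if "quantgen" in config.stages:
        resid = cov.residualize(cohort, "genetic")
        sub = resid.iloc[:, : config.quantgen_max_parcels]
        transformed = sub.apply(lambda c: qg.inverse_normal_transform(c.to_numpy()), axis=0)
        ae = qg.genetic_correlation_matrix(transformed, cohort.pedigree)
        np.savetxt(out / "h2.tsv", ae.h2, delimiter="\t")
        for name, m in (("rho_g", ae.rho_g), ("rho_e", ae.rho_e), ("rho_p", ae.rho_p)):
            kind = (
                "genetic_correlation" if name == "rho_g"
                else "environmental_correlation" if name == "rho_e"
                else "phenotypic_correlation"
            )
            spm = SymmetricParcelMatrix(
                values=np.clip(m, -1, 1), kind=kind, parcel_ids=ae.parcel_ids,
                meta={"n_failed": ae.n_failed},
            )
            write_matrix(spm, out / f"{name}.tsv")
        report["quantgen"] = {"h2_mean": float(np.mean(ae.h2)), "n_failed": ae.n_failed}

    gset = None
    if "gradients" in config.stages:
        if matrix is None:
            resid = cov.residualize(cohort, config.covariate_preset)
            matrix = cov.structural_covariance(resid)
        gset = grad.gradients_from_matrix(
            matrix, n_components=config.n_components,
            keep_fraction=config.keep_fraction, alpha=config.alpha,
        )
        np.savetxt(out / "gradients.tsv", gset.coords, delimiter="\t")
        _sidecar(
            out / "gradients.tsv",
            eigenvalues=gset.eigenvalues.tolist(),
            variance_explained=gset.variance_explained.tolist(),
            alpha=config.alpha, keep_fraction=config.keep_fraction,
        )
        bins = grad.bin_gradient(gset.coords[:, 0], matrix, n_bins=config.n_bins)
        np.savetxt(out / "gradient_bins.tsv", bins.bin_matrix, delimiter="\t")
        report["gradients"] = {
            "variance_explained": gset.variance_explained[:2].tolist(),
            "r_g1_vs_planted": float(
                abs(np.corrcoef(gset.coords[:, 0], truth.g1_axis)[0, 1])
            ),
        }

    if "spatial" in config.stages and gset is not None:
        r, p_spin, _ = spatial.spin_test(
            gset.coords[:, 0], truth.g1_axis, geom,
            n_rotations=config.n_rotations, seed=seeds["spatial"],
        )
        fields = spatial.distance_fields(geom)
        dual = spatial.dual_origin_association(
            gset.coords[:, 1] if gset.coords.shape[1] > 1 else gset.coords[:, 0],
            fields, geom, n_rotations=config.n_rotations,
            n_perm=config.n_perm, seed=seeds["spatial"],
        )
        report["spatial"] = {
            "spin_r_g1_vs_planted": r,
            "spin_p": p_spin,
            "dual_origin": {
                "energy": {k: list(v) for k, v in dual.energy.items()},
                "linear": {k: list(v) for k, v in dual.linear.items()},
            },
        }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    log.info("pipeline complete: %s", out)
    return out
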