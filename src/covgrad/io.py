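"""Standard-format I/O: matrices (TSV + JSON sidecar), cohorts
(phenotype TSV + pedigree CSV), meshes (PLY / GIFTI), geometry bundles
and ground-truth archives."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import ParcelGeometry
from .matrices import SymmetricParcelMatrix
from .simulate import GroundTruth, GroundTruthParams, TwinCohort


# ---------------------------------------------------------------------------
# matrices


def write_matrix(mat: SymmetricParcelMatrix, path: str | Path) -> None:
    """TSV with parcel-id header row/column; metadata in a .json sidecar."""
    path = Path(path)
    df = pd.DataFrame(mat.values, index=mat.parcel_ids, columns=mat.parcel_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")
    sidecar = {"kind": mat.kind, "meta": _jsonable(mat.meta)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix(path: str | Path) -> SymmetricParcelMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    sidecar_path = path.with_suffix(path.suffix + ".json")
    kind, meta = "covariance", {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        kind = sidecar.get("kind", kind)
        meta = sidecar.get("meta", {})
    return SymmetricParcelMatrix(
        values=df.to_numpy(float), kind=kind, parcel_ids=df.columns.to_numpy(), meta=meta
    )


# ---------------------------------------------------------------------------
# cohorts


def write_cohort(cohort: TwinCohort, phenotypes_path: str | Path, pedigree_path: str | Path) -> None:
    """Phenotypes as subjects x parcels TSV (header = parcel ids), pedigree
    as CSV (subject_id, family_id, zygosity, age, sex, site)."""
    cohort.thickness.to_csv(phenotypes_path, sep="\t", float_format="%.17g")
    cohort.pedigree.to_csv(pedigree_path, index=False)


def read_cohort(phenotypes_path: str | Path, pedigree_path: str | Path) -> TwinCohort:
    try:
        thickness = pd.read_csv(phenotypes_path, sep="\t", index_col=0, float_precision="round_trip")
        pedigree = pd.read_csv(pedigree_path)
    except Exception as exc:
        raise ValueError(f"malformed cohort files: {exc}") from exc
    return TwinCohort(pedigree=pedigree, thickness=thickness)


# ---------------------------------------------------------------------------
# meshes and geometry


def read_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Vertices/faces from a PLY or GIFTI surface file."""
    path = Path(path)
    if path.suffix.lower() == ".gii":
        import nibabel as nib

        img = nib.load(str(path))
        arrays = {d.intent: d.data for d in img.darrays}
        from nibabel.nifti1 import intent_codes

        pointset = intent_codes["NIFTI_INTENT_POINTSET"]
        triangle = intent_codes["NIFTI_INTENT_TRIANGLE"]
        verts = np.asarray(arrays[pointset], dtype=float)
        faces = np.asarray(arrays[triangle], dtype=int)
        return verts, faces
    mesh = trimesh.load(str(path), process=False)
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)


def write_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """Write a triangle mesh as PLY (ascii) or GIFTI by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".gii":
        import nibabel as nib
        from nibabel.gifti import GiftiDataArray, GiftiImage

        img = GiftiImage(
            darrays=[
                GiftiDataArray(np.asarray(vertices, dtype=np.float32), intent="NIFTI_INTENT_POINTSET"),
                GiftiDataArray(np.asarray(faces, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE"),
            ]
        )
        nib.save(img, str(path))
        return
    mesh = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))


def write_geometry(geom: ParcelGeometry, out_dir: str | Path, mesh_format: str = "ply") -> None:
    """Mesh (PLY or GIFTI), parcel-map CSV, and parcel table CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mesh(geom.mesh.vertices, geom.mesh.faces, out / f"mesh.{mesh_format}")
    pd.DataFrame(
        {"vertex": np.arange(len(geom.vertex_to_parcel)), "parcel": geom.vertex_to_parcel}
    ).to_csv(out / "vertex_to_parcel.csv", index=False)
    pd.DataFrame(
        {
            "parcel_id": geom.parcel_ids,
            "hemisphere": geom.hemisphere,
            "community": geom.community,
            "cx": geom.centroids[:, 0],
            "cy": geom.centroids[:, 1],
            "cz": geom.centroids[:, 2],
        }
    ).to_csv(out / "parcels.csv", index=False)
    seeds = {k: v.tolist() for k, v in geom.seed_points.items()}
    (out / "seed_points.json").write_text(json.dumps(seeds))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Compressed matrix archive (.npz) plus a JSON manifest."""
    path = Path(path)
    np.savez_compressed(
        path,
        sigma_g=truth.sigma_g,
        sigma_e=truth.sigma_e,
        h2_true=truth.h2_true,
        rho_g_true=truth.rho_g_true,
        rho_e_true=truth.rho_e_true,
        g1_axis=truth.g1_axis,
        g2_axis=truth.g2_axis,
    )
    manifest = {
        "params": _jsonable(vars(truth.params)),
        "betas": _jsonable(truth.betas),
        "arrays": ["sigma_g", "sigma_e", "h2_true", "rho_g_true", "rho_e_true", "g1_axis", "g2_axis"],
    }
    Path(str(path) + ".json").write_text(json.dumps(manifest, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = np.load(path)
    manifest_path = Path(str(path) + ".json")
    params = GroundTruthParams()
    betas = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        params = GroundTruthParams(**manifest.get("params", {}))
        betas = {k: np.asarray(v) for k, v in manifest.get("betas", {}).items()}
    return GroundTruth(
        sigma_g=data["sigma_g"],
        sigma_e=data["sigma_e"],
        h2_true=data["h2_true"],
        rho_g_true=data["rho_g_true"],
        rho_e_true=data["rho_e_true"],
        g1_axis=data["g1_axis"],
        g2_axis=data["g2_axis"],
        betas=betas,
        params=params,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
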