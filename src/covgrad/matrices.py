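"""Shared parcel-by-parcel matrix container with provenance metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KINDS = {
    "covariance",
    "genetic_correlation",
    "environmental_correlation",
    "phenotypic_correlation",
    "distance",
    "affinity",
    "mpc",
}

_CORRELATION_KINDS = {
    "genetic_correlation",
    "environmental_correlation",
    "phenotypic_correlation",
}


@dataclass
class SymmetricParcelMatrix:
    """p x p symmetric matrix over an ordered parcel set.

    ``kind`` declares the semantics (covariance / correlation / distance /
    affinity / mpc) and drives validation; ``meta`` carries provenance
    (covariates removed, number of subjects, site control, ...).
    """

    values: np.ndarray
    kind: str
    parcel_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.parcel_ids = np.asarray(self.parcel_ids)
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        p = len(self.parcel_ids)
        if self.values.shape != (p, p):
            raise ValueError(
                f"values shape {self.values.shape} does not match {p} parcel ids"
            )
        finite = np.isfinite(self.values)
        sym_ok = np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite.T, self.values.T, 0.0),
            atol=1e-10,
        ) and np.array_equal(finite, finite.T)
        if not sym_ok:
            raise ValueError("matrix is not symmetric within 1e-10")
        vals = self.values[finite]
        if self.kind in _CORRELATION_KINDS:
            if np.nanmax(np.abs(self.values)) > 1 + 1e-8:
                raise ValueError("correlation entries must lie in [-1, 1]")
            if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
                raise ValueError("correlation matrix must have unit diagonal")
        if self.kind == "distance":
            if vals.size and vals.min() < -1e-12:
                raise ValueError("distances must be non-negative")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
                raise ValueError("distance matrix must have zero diagonal")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    def copy_with(self, values: np.ndarray, kind: str | None = None, **meta) -> "SymmetricParcelMatrix":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return SymmetricParcelMatrix(
            values=values, kind=kind or self.kind, parcel_ids=self.parcel_ids, meta=new_meta
        )
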