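"""Point-distribution (statistical shape) model of corresponded meshes.

A shape with J vertices is flattened to a 3J shape parameter vector
p = (v1x, v1y, v1z, ..., vJx, vJy, vJz).  Over n training shapes the model
is the mean p̄ = (1/n) Σ p_i together with the eigenpairs of the empirical
covariance S = (1/n) Σ (p_i − p̄)(p_i − p̄)ᵀ.  The 1/n normalization (not
1/(n−1)) is deliberate and documented; users comparing against
sample-covariance tools should expect the constant factor (n−1)/n.

Eigenpairs are computed by the snapshot method — the n×n Gram matrix of
centered shape vectors — so the 3J×3J covariance (3J can exceed 10⁵) is
never materialized.  At most k = n − 1 eigenvalues are nonzero.

New shapes are generated as p = p̄ + Σ_j c_j · sd_j · q_j where
sd_j = sqrt(λ_j) and the weights c_j are dimensionless standard-deviation
multiples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .correspondence import CorrespondedShapeSet
from .meshes import VolumetricMesh

__all__ = [
    "ShapeParameterVector",
    "StatisticalShapeModel",
    "DegenerateModelError",
    "to_shape_vector",
    "from_shape_vector",
    "fit_ssm",
    "variance_explained",
    "reconstruct",
    "variation_model",
    "project",
    "save_model",
    "load_model",
]

#: eigenvalues below this fraction of the largest are treated as zero
EIGENVALUE_RTOL = 1e-10


class DegenerateModelError(ValueError):
    """All eigenvalues are zero: the training set has no shape variance."""


@dataclass
class ShapeParameterVector:
    """A flattened shape: 3J scalars in v1x, v1y, v1z, ..., vJx, vJy, vJz order."""

    values: np.ndarray
    J: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.values) != 3 * self.J:
            raise ValueError(
                f"shape vector has {len(self.values)} entries, expected 3J = {3 * self.J}"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_vertices(self) -> np.ndarray:
        return self.values.reshape(self.J, 3)


def to_shape_vector(mesh) -> ShapeParameterVector:
    """Flatten a mesh (VolumetricMesh or (J, 3) array) into a shape vector."""
    coords = mesh.nodes if isinstance(mesh, VolumetricMesh) else np.asarray(mesh, float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("expected (J, 3) coordinates")
    return ShapeParameterVector(values=coords.ravel().copy(), J=len(coords))


def from_shape_vector(vector: ShapeParameterVector | np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_shape_vector`: (J, 3) coordinates."""
    if isinstance(vector, ShapeParameterVector):
        return vector.as_vertices().copy()
    v = np.asarray(vector, float).ravel()
    if len(v) % 3:
        raise ValueError("flat shape vector length must be a multiple of 3")
    return v.reshape(-1, 3)


@dataclass
class StatisticalShapeModel:
    """Mean shape, orthonormal shape modes and eigenvalues of the covariance.

    ``mean``: (3J,) mm.  ``modes``: (k, 3J), unit length, mutually
    orthogonal.  ``eigenvalues``: (k,) mm², descending.  ``n_train``:
    number of training shapes; k ≤ n_train − 1.
    """

    mean: np.ndarray
    modes: np.ndarray
    eigenvalues: np.ndarray
    n_train: int
    J: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float).ravel()
        self.modes = np.atleast_2d(np.asarray(self.modes, float))
        self.eigenvalues = np.asarray(self.eigenvalues, float).ravel()
        if len(self.mean) != 3 * self.J:
            raise ValueError("mean length must be 3J")
        if self.modes.shape[0] != len(self.eigenvalues):
            raise ValueError("one eigenvalue per mode required")
        if self.modes.shape[0] and self.modes.shape[1] != 3 * self.J:
            raise ValueError("modes must have length 3J")
        if self.n_modes > self.n_train - 1:
            raise ValueError("more than n_train - 1 modes")
        if (self.eigenvalues < 0).any():
            raise ValueError("negative eigenvalue")
        if np.any(np.diff(self.eigenvalues) > 0):
            raise ValueError("eigenvalues must be sorted descending")
        if self.n_modes:
            gram = self.modes @ self.modes.T
            if not np.allclose(gram, np.eye(self.n_modes), atol=1e-8):
                raise ValueError("modes are not orthonormal to 1e-8")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


def fit_ssm(shape_set: CorrespondedShapeSet) -> StatisticalShapeModel:
    """Fit the point-distribution model to a corresponded shape set.

    Uses the snapshot (Gram-matrix) eigendecomposition; modes whose
    eigenvalue falls below ``EIGENVALUE_RTOL`` times the largest are
    dropped, leaving at most n − 1 modes.
    """
    n, J = shape_set.n, shape_set.J
    P = shape_set.shapes.reshape(n, 3 * J)
    mean = P.mean(axis=0)
    A = P - mean
    gram = (A @ A.T) / n  # n×n stand-in for the 3J×3J covariance
    evals, evecs = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    cutoff = EIGENVALUE_RTOL * evals[0] if evals[0] > 0 else 0.0
    keep = min(n - 1, int(np.sum(evals > cutoff))) if evals[0] > 0 else 0
    evals = evals[:keep]
    modes = np.zeros((keep, 3 * J))
    for k in range(keep):
        q = A.T @ evecs[:, k]
        q /= np.linalg.norm(q)
        # sign convention: largest-magnitude component positive
        imax = np.argmax(np.abs(q))
        if q[imax] < 0:
            q = -q
        modes[k] = q
    return StatisticalShapeModel(
        mean=mean, modes=modes, eigenvalues=evals, n_train=n, J=J
    )


def variance_explained(model: StatisticalShapeModel) -> np.ndarray:
    """Fraction of total variance per mode: λ_k / Σλ, descending, summing to 1."""
    total = model.eigenvalues.sum()
    if model.n_modes == 0 or total <= 0:
        raise DegenerateModelError("degenerate model: all eigenvalues are zero")
    return model.eigenvalues / total


def reconstruct(
    model: StatisticalShapeModel, weights: np.ndarray
) -> ShapeParameterVector:
    """Generate p = p̄ + Σ_j c_j · sqrt(λ_j) · q_j for weights c (length m ≤ k)."""
    c = np.asarray(weights, float).ravel()
    if len(c) > model.n_modes:
        raise ValueError(
            f"{len(c)} weights given but model has {model.n_modes} modes"
        )
    values = model.mean.copy()
    if len(c):
        sd = np.sqrt(model.eigenvalues[: len(c)])
        values = values + (c * sd) @ model.modes[: len(c)]
    return ShapeParameterVector(values=values, J=model.J)


def variation_model(
    model: StatisticalShapeModel, mode_index: int, n_sd: float
) -> ShapeParameterVector:
    """Mean shape displaced by ``n_sd`` standard deviations along one mode."""
    if not 0 <= mode_index < model.n_modes:
        raise IndexError(f"mode_index {mode_index} out of range [0, {model.n_modes})")
    c = np.zeros(model.n_modes)
    c[mode_index] = n_sd
    return reconstruct(model, c)


def project(model: StatisticalShapeModel, shape) -> np.ndarray:
    """Standardized mode scores c_j of a shape: (p − p̄)·q_j / sqrt(λ_j)."""
    p = to_shape_vector(shape).values if not isinstance(shape, ShapeParameterVector) else shape.values
    d = p - model.mean
    sd = np.sqrt(model.eigenvalues)
    return (model.modes @ d) / sd


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

_FORMAT_TAG = "spinessm-ssm-1"


def save_model(model: StatisticalShapeModel, path: str | Path) -> None:
    """Store mean, modes, eigenvalues, J and n_train with a format version tag."""
    np.savez(
        Path(path),
        format=np.array(_FORMAT_TAG),
        mean=model.mean,
        modes=model.modes,
        eigenvalues=model.eigenvalues,
        n_train=np.array(model.n_train),
        J=np.array(model.J),
    )


def load_model(path: str | Path) -> StatisticalShapeModel:
    with np.load(Path(path)) as data:
        tag = str(data["format"])
        if tag != _FORMAT_TAG:
            raise IOError(f"unrecognized model format tag {tag!r}")
        return StatisticalShapeModel(
            mean=data["mean"],
            modes=data["modes"],
            eigenvalues=data["eigenvalues"],
            n_train=int(data["n_train"]),
            J=int(data["J"]),
        )
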