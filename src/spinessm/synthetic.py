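"""Synthetic inputs with known ground truth.

Real cervical-spine CT segmentations and cadaver moment-rotation data are
not redistributable, so every pipeline stage is exercised against
generated stand-ins: corresponded vertebra-like surface sets drawn from a
planted low-rank shape model, and surrogate moment-rotation curves with a
ligamentous "slack" region near zero moment.  Generator defaults mirror
the study design this toolkit targets — five training spines, seven
experimental specimens, one hundred probabilistic model samples, moments
sampled at 0.33/0.5/1.0/1.5/2.0 Nm — so tests exercise the same shapes of
data as a real analysis.  All generators take explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .correspondence import CorrespondedShapeSet
from .meshes import TriangleSurface
from .validation import MOMENT_LEVELS_NM, MomentRotationResponse

__all__ = [
    "PlantedShapeModel",
    "SurrogateResponseParams",
    "make_planted_model",
    "make_shape_set",
    "make_vertebra_surface",
    "make_response_samples",
    "default_moment_grid",
]


@dataclass
class PlantedShapeModel:
    """Ground-truth generative shape model: mean + known orthonormal modes.

    ``mean`` is (J, 3) mm; ``true_modes`` (m, 3J) orthonormal;
    ``true_sds`` per-mode standard deviations (mm); ``noise_sd``
    independent per-coordinate Gaussian noise (mm).
    """

    mean: np.ndarray
    true_modes: np.ndarray
    true_sds: np.ndarray
    noise_sd: float
    seed: int
    faces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.true_modes = np.atleast_2d(np.asarray(self.true_modes, float))
        self.true_sds = np.asarray(self.true_sds, float).ravel()
        if self.mean.ndim != 2 or self.mean.shape[1] != 3:
            raise ValueError("mean must be (J, 3)")
        m, dim = self.true_modes.shape
        if dim != 3 * len(self.mean) or len(self.true_sds) != m:
            raise ValueError("modes must be (m, 3J) with one sd per mode")
        gram = self.true_modes @ self.true_modes.T
        if not np.allclose(gram, np.eye(m), atol=1e-8):
            raise ValueError("true_modes must be orthonormal")
        if np.any(self.true_sds < 0) or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")


def make_planted_model(
    base: TriangleSurface,
    n_modes: int,
    sds,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PlantedShapeModel:
    """Plant ``n_modes`` random orthonormal smooth-ish modes on a base surface."""
    rng = np.random.default_rng(seed)
    dim = 3 * base.vertex_count
    raw = rng.standard_normal((dim, n_modes))
    q, _ = np.linalg.qr(raw)
    return PlantedShapeModel(
        mean=base.vertices.copy(),
        true_modes=q.T,
        true_sds=np.broadcast_to(np.asarray(sds, float), (n_modes,)).copy(),
        noise_sd=noise_sd,
        seed=seed,
        faces=base.faces.copy(),
    )


def make_shape_set(planted: PlantedShapeModel, n_shapes: int) -> CorrespondedShapeSet:
    """Draw a corresponded shape set from a planted model.

    Shape i = mean + Σ_j z_ij · sd_j · mode_j + noise with z standard
    normal under the planted seed; identical seeds give identical sets.
    """
    if n_shapes < 2:
        raise ValueError("n_shapes must be >= 2")
    rng = np.random.default_rng(planted.seed)
    J = len(planted.mean)
    m = len(planted.true_sds)
    z = rng.standard_normal((n_shapes, m))
    flat = planted.mean.ravel() + (z * planted.true_sds) @ planted.true_modes
    if planted.noise_sd > 0:
        flat = flat + planted.noise_sd * rng.standard_normal(flat.shape)
    faces = planted.faces if planted.faces is not None else np.zeros((0, 3), int)
    return CorrespondedShapeSet(shapes=flat.reshape(n_shapes, J, 3), faces=faces)


def make_vertebra_surface(
    body_radii=(18.0, 14.0, 10.0),
    process_length: float = 15.0,
    resolution: int = 4,
) -> TriangleSurface:
    """A closed vertebra-like surface: ellipsoidal body + posterior protrusion.

    Built by radially deforming an icosphere: the unit sphere is scaled to
    the ellipsoidal "body" (semi-axes ``body_radii`` mm along x, y, z) and
    vertices facing the posterior (−y) direction are pushed outward to
    form a smooth spinous-process-like protrusion of extra length
    ``process_length`` mm.  Deterministic; face count grows as
    20 · 4^resolution.
    """
    if min(body_radii) <= 0 or process_length < 0 or resolution < 0:
        raise ValueError("dimensions must be positive")
    ico = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    d = np.asarray(ico.vertices)  # unit directions
    verts = d * np.asarray(body_radii, float)
    if process_length > 0:
        # smooth bump for directions within the posterior cone d_y < -0.7
        w = np.clip((-d[:, 1] - 0.7) / 0.3, 0.0, 1.0) ** 2
        verts = verts + (process_length * w)[:, None] * d
    return TriangleSurface(
        vertices=verts, faces=np.asarray(ico.faces, np.int64), label="synthetic_vertebra"
    )


@dataclass
class SurrogateResponseParams:
    """Parameters of the surrogate moment-rotation generator.

    slack_angle
        Rotation (degrees) taken up by the low-stiffness slack region
        around 0 Nm (ligamentous laxity).
    stiffness
        Linear stiffness (Nm/degree) beyond the slack region.
    asymmetry
        Rotation-magnitude ratio of the negative (extension/right) branch
        to the positive branch; 1 gives an odd-symmetric response.
    noise_sd
        Additive measurement noise SD (degrees) per recorded point.
    jitter_cv
        Coefficient of variation of per-sample lognormal jitter applied to
        slack angle and compliance (specimen-to-specimen variability).
    """

    slack_angle: float = 3.0
    stiffness: float = 0.25
    asymmetry: float = 1.0
    noise_sd: float = 0.0
    jitter_cv: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slack_angle < 0 or self.stiffness <= 0:
            raise ValueError("slack_angle >= 0 and stiffness > 0 required")
        if self.asymmetry <= 0 or self.noise_sd < 0 or self.jitter_cv < 0:
            raise ValueError("asymmetry > 0; noise_sd, jitter_cv >= 0 required")


#: moment (Nm) over which the slack region saturates
_SLACK_SCALE_NM = 0.1


def default_moment_grid() -> np.ndarray:
    """Signed moment grid ±(0.33 … 2.0) Nm plus 0, ascending."""
    pos = np.asarray(MOMENT_LEVELS_NM, float)
    return np.concatenate([-pos[::-1], [0.0], pos])


def _lognormal_jitter(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size)


def make_response_samples(
    params: SurrogateResponseParams,
    n_samples: int,
    moment_grid=None,
    mode: str = "flexion_extension",
    source: str = "model_sample",
) -> list[MomentRotationResponse]:
    """Generate surrogate moment-rotation sweeps.

    Each sample follows rotation(M) = s·[slack·|M|/(|M| + 0.1) + |M|/k]
    with s the sign of M (scaled by ``asymmetry`` on the negative branch):
    a saturating near-zero-stiffness slack region followed by a linear
    limb.  slack and 1/k are jittered per sample (lognormal,
    ``jitter_cv``), and Gaussian noise of SD ``noise_sd`` is added per
    point.  Noise-free responses are strictly monotone in the applied
    moment; with ``slack_angle = 0`` and no jitter the response is exactly
    M / stiffness.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    grid = np.asarray(
        default_moment_grid() if moment_grid is None else moment_grid, float
    )
    rng = np.random.default_rng(params.seed)
    slack_i = params.slack_angle * _lognormal_jitter(rng, params.jitter_cv, n_samples)
    compl_i = (1.0 / params.stiffness) * _lognormal_jitter(
        rng, params.jitter_cv, n_samples
    )
    out = []
    absM = np.abs(grid)
    sign = np.where(grid < 0, -params.asymmetry, 1.0)
    sign[grid == 0] = 0.0
    for i in range(n_samples):
        mag = slack_i[i] * absM / (absM + _SLACK_SCALE_NM) + compl_i[i] * absM
        rot = sign * mag
        if params.noise_sd > 0:
            rot = rot + params.noise_sd * rng.standard_normal(rot.shape)
        out.append(
            MomentRotationResponse(
                moments=grid.copy(), rotations=rot, mode=mode, source=source
            )
        )
    return out
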