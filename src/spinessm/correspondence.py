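"""Vertex correspondence, shape averaging, volumetric warping, spine registration.

Correspondence is established by mapping a template surface onto each
target with nonrigid coherent point drift (CPD): the template point set
moves as a group under a Gaussian-kernel smooth displacement field fit by
expectation-maximization, so template vertex *j* lands on the anatomically
matching location of every target and all shapes share one mesh topology.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RBFInterpolator

from .meshes import (
    MeshValidationError,
    TriangleSurface,
    VolumetricMesh,
    tet_signed_volumes,
)

__all__ = [
    "CPDParams",
    "RegistrationError",
    "CorrespondedShapeSet",
    "register_nonrigid",
    "build_corresponded_set",
    "average_shape",
    "warp_volumetric_mesh",
    "center_spine",
    "save_corresponded_set",
    "load_corresponded_set",
]


class RegistrationError(RuntimeError):
    """Nonrigid registration failed to converge or to reach the target surface."""


@dataclass
class CPDParams:
    """Settings for nonrigid coherent point drift.

    smoothness
        Regularization weight (λ) on the displacement field; larger values
        give stiffer, more coherent motion.
    kernel_width
        Gaussian kernel width (β) in normalized (unit-scale) coordinates.
    outlier_weight
        Uniform-outlier mixture weight w ∈ [0, 1).
    max_iterations, convergence_tol
        EM stops when the relative change of σ² falls below
        ``convergence_tol`` or after ``max_iterations`` steps.
    tolerance
        Acceptance bound (mm) on the mean nearest-point distance from the
        registered vertices to the target vertices.
    pre_align
        ``"centroid"`` translates the template centroid onto the target
        centroid before CPD (recommended for pre-posed anatomical scans);
        ``"none"`` disables it.
    """

    smoothness: float = 2.0
    kernel_width: float = 2.0
    outlier_weight: float = 0.0
    max_iterations: int = 300
    convergence_tol: float = 1e-8
    tolerance: float = 1.0
    pre_align: str = "centroid"


def _gaussian_kernel(y: np.ndarray, beta: float) -> np.ndarray:
    d2 = np.sum((y[:, None, :] - y[None, :, :]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * beta**2))


def register_nonrigid(
    template: TriangleSurface | np.ndarray,
    target: TriangleSurface | np.ndarray,
    params: CPDParams | None = None,
) -> np.ndarray:
    """Map ``template`` vertices onto ``target`` with nonrigid CPD.

    Returns a (J, 3) array: one repositioned coordinate per template
    vertex, in template vertex order, lying on the target surface to
    within ``params.tolerance`` mm (mean nearest-point distance).
    """
    params = params or CPDParams()
    Y0 = np.asarray(
        template.vertices if isinstance(template, TriangleSurface) else template,
        dtype=float,
    )
    X0 = np.asarray(
        target.vertices if isinstance(target, TriangleSurface) else target,
        dtype=float,
    )
    if len(Y0) < 10 or len(X0) < 10:
        raise ValueError("template and target each need at least 10 vertices")

    shift = np.zeros(3)
    if params.pre_align == "centroid":
        shift = X0.mean(axis=0) - Y0.mean(axis=0)
    Y_pre = Y0 + shift

    # normalize jointly so kernel width and σ² are scale-free
    mu = X0.mean(axis=0)
    scale = max(np.sqrt(((X0 - mu) ** 2).sum(axis=1).mean()), 1e-12)
    X = (X0 - mu) / scale
    Y = (Y_pre - mu) / scale

    M, N = len(Y), len(X)
    G = _gaussian_kernel(Y, params.kernel_width)
    W = np.zeros((M, 3))
    T = Y.copy()
    sigma2 = np.sum((X[None, :, :] - Y[:, None, :]) ** 2) / (3.0 * M * N)
    w = params.outlier_weight
    converged = False
    for _ in range(params.max_iterations):
        # E-step: soft assignment of target points to template points
        d2 = np.sum((X[None, :, :] - T[:, None, :]) ** 2, axis=2)
        num = np.exp(-d2 / (2.0 * sigma2))
        c = (
            (2.0 * np.pi * sigma2) ** 1.5 * w / max(1.0 - w, 1e-12) * M / N
        )
        den = num.sum(axis=0) + c
        den[den == 0] = np.finfo(float).tiny
        P = num / den
        P1 = P.sum(axis=1)
        Pt1 = P.sum(axis=0)
        Np = P1.sum()
        if Np <= 0:
            break
        PX = P @ X
        # M-step: smooth displacement coefficients
        A = G * P1[:, None] + params.smoothness * sigma2 * np.eye(M)
        B = PX - P1[:, None] * Y
        W = np.linalg.solve(A, B)
        T = Y + G @ W
        sigma2_new = (
            np.sum(Pt1 * np.sum(X * X, axis=1))
            - 2.0 * np.sum(PX * T)
            + np.sum(P1 * np.sum(T * T, axis=1))
        ) / (3.0 * Np)
        sigma2_new = max(sigma2_new, 1e-14)
        if abs(sigma2 - sigma2_new) < params.convergence_tol * max(sigma2, 1e-30):
            sigma2 = sigma2_new
            converged = True
            break
        sigma2 = sigma2_new

    out = T * scale + mu
    from scipy.spatial import cKDTree

    mean_dist = float(cKDTree(X0).query(out)[0].mean())
    if not converged and mean_dist > params.tolerance:
        raise RegistrationError(
            f"CPD did not converge in {params.max_iterations} iterations; "
            f"mean residual distance {mean_dist:.4g} mm"
        )
    if mean_dist > params.tolerance:
        raise RegistrationError(
            f"registered vertices lie {mean_dist:.4g} mm (mean) from the target, "
            f"exceeding tolerance {params.tolerance} mm"
        )
    return out


@dataclass
class CorrespondedShapeSet:
    """n shapes sharing one mesh topology with vertex-wise correspondence.

    ``shapes`` is (n, J, 3) in mm; ``faces`` the shared triangulation;
    ``labels`` one identifier per anatomical component (optional).
    """

    shapes: np.ndarray
    faces: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.shapes = np.asarray(self.shapes, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.shapes.ndim != 3 or self.shapes.shape[2] != 3:
            raise MeshValidationError("shapes must be (n, J, 3)")
        if self.n < 2:
            raise MeshValidationError("a corresponded set needs n >= 2 shapes")
        if len(self.faces) and self.faces.max() >= self.J:
            raise MeshValidationError("shared faces reference missing vertices")

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def J(self) -> int:
        return self.shapes.shape[1]

    def surface(self, i: int) -> TriangleSurface:
        return TriangleSurface(vertices=self.shapes[i], faces=self.faces)


def build_corresponded_set(
    surfaces: list[TriangleSurface],
    template_index: int,
    params: CPDParams | None = None,
) -> CorrespondedShapeSet:
    """Register one template onto every surface of a set at one level.

    The template's own entry is its vertices verbatim; every other entry
    is the CPD-repositioned template, so all shapes share the template
    topology.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces")
    if not 0 <= template_index < len(surfaces):
        raise IndexError(f"template_index {template_index} out of range")
    template = surfaces[template_index]
    shapes = np.empty((len(surfaces), template.vertex_count, 3))
    for i, surf in enumerate(surfaces):
        if i == template_index:
            shapes[i] = template.vertices
            continue
        try:
            shapes[i] = register_nonrigid(template, surf, params)
        except RegistrationError as exc:
            raise RegistrationError(
                f"registration of template onto surface {i} "
                f"({surf.label or 'unlabeled'}) failed: {exc}"
            ) from exc
    return CorrespondedShapeSet(
        shapes=shapes, faces=template.faces.copy(), labels=[template.label]
    )


def average_shape(shape_set: CorrespondedShapeSet) -> np.ndarray:
    """Vertex-wise arithmetic mean shape, (J, 3)."""
    return shape_set.shapes.mean(axis=0)


def warp_volumetric_mesh(
    average_mesh: VolumetricMesh,
    surface_displacements: np.ndarray,
    check_inversion: bool = True,
) -> VolumetricMesh:
    """Warp a tet mesh by prescribed boundary-node displacements.

    Surface nodes move exactly by ``surface_displacements`` (one 3-vector
    per entry of ``average_mesh.surface_node_ids``, in that order); the
    interior follows a thin-plate-spline radial-basis interpolant with an
    affine term, which reproduces affine fields exactly.  Connectivity is
    unchanged.  Raises if the warp inverts any tet.
    """
    disp = np.asarray(surface_displacements, dtype=float)
    sid = average_mesh.surface_node_ids
    if disp.shape != (len(sid), 3):
        raise ValueError(
            f"expected displacements of shape ({len(sid)}, 3), got {disp.shape}"
        )
    nodes = average_mesh.nodes.copy()
    if np.allclose(disp, 0.0):
        new_nodes = nodes
    else:
        interp = RBFInterpolator(
            nodes[sid], disp, kernel="thin_plate_spline", degree=1
        )
        new_nodes = nodes + interp(nodes)
        new_nodes[sid] = nodes[sid] + disp  # exact on the boundary
    warped = VolumetricMesh.__new__(VolumetricMesh)
    warped.nodes = new_nodes
    warped.tets = average_mesh.tets.copy()
    warped.surface_node_ids = sid.copy()
    if check_inversion:
        vols = tet_signed_volumes(warped.nodes, warped.tets)
        bad = np.where(vols <= 0)[0]
        if len(bad):
            raise MeshValidationError(
                f"warp inverted {len(bad)} tets: {bad[:20].tolist()}"
            )
    return warped


def _component_nodes(component) -> np.ndarray:
    return component.nodes if isinstance(component, VolumetricMesh) else np.asarray(component, float)


def center_spine(spine: list, central_component_index: int) -> list:
    """Translate a multi-component spine so the central component's centroid is 0.

    Accepts a list of ``VolumetricMesh`` or raw (J, 3) vertex arrays;
    relative positions between components are preserved exactly.
    """
    if not 0 <= central_component_index < len(spine):
        raise IndexError("central_component_index out of range")
    centroid = _component_nodes(spine[central_component_index]).mean(axis=0)
    out = []
    for comp in spine:
        if isinstance(comp, VolumetricMesh):
            out.append(
                VolumetricMesh(
                    nodes=comp.nodes - centroid,
                    tets=comp.tets.copy(),
                    surface_node_ids=comp.surface_node_ids.copy(),
                )
            )
        else:
            out.append(np.asarray(comp, float) - centroid)
    return out


# ---------------------------------------------------------------------------
# corresponded-set persistence: per-shape vertex tables + shared face table
# ---------------------------------------------------------------------------


def save_corresponded_set(shape_set: CorrespondedShapeSet, out_dir: str | Path) -> None:
    """Write a set directory: manifest.json, faces.txt, shape_###.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "spinessm-corresponded-set-1",
        "units": "mm",
        "n": shape_set.n,
        "J": shape_set.J,
        "labels": shape_set.labels,
        "shapes": [f"shape_{i:03d}.txt" for i in range(shape_set.n)],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(out / "faces.txt", shape_set.faces, fmt="%d")
    for i in range(shape_set.n):
        np.savetxt(out / f"shape_{i:03d}.txt", shape_set.shapes[i], fmt="%.9g")


def load_corresponded_set(in_dir: str | Path) -> CorrespondedShapeSet:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    faces = np.loadtxt(src / "faces.txt", dtype=np.int64).reshape(-1, 3)
    shapes = np.stack(
        [np.loadtxt(src / name).reshape(-1, 3) for name in manifest["shapes"]]
    )
    return CorrespondedShapeSet(
        shapes=shapes, faces=faces, labels=list(manifest.get("labels", []))
    )
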