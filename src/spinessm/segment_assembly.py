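"""Soft-tissue and joint geometry attached to corresponded vertebral meshes.

Builds the pieces of a spine motion segment that sit between the bones:
intervertebral-disk boundary curves on the endplates, the nucleus/annulus
interface ellipse, facet cartilage layers extruded to maximal thickness
without interference, ligament spring attachments carried across
individuals by vertex correspondence, and the disk material records.

Volumetric (hexahedral) disk meshing and constitutive evaluation are out
of scope; the outputs here are the bounding curves/surfaces and exportable
parameter records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from ._intersect import any_triangles_intersect
from .correspondence import CorrespondedShapeSet
from .meshes import TriangleSurface, open_boundary_edges

__all__ = [
    "ClosedCurve",
    "LigamentSpec",
    "MaterialSpec",
    "InterferenceError",
    "fit_boundary_curve",
    "nucleus_ellipse",
    "facet_cartilage_thickness",
    "attach_ligaments",
    "scale_load_curve",
    "synthetic_load_curve",
    "default_material_spec",
    "ANNULUS_PRONY",
    "NUCLEUS_PROPERTIES",
    "DISK_BULK_MODULUS_MPA",
    "LIGAMENT_KINDS",
    "LEVEL_GROUPS",
]

LIGAMENT_KINDS = ("ALL", "PLL", "ISL", "LF", "JC", "ITL")
LEVEL_GROUPS = ("C3-C5", "C5-T1")

#: annulus Prony-series coefficients (S_i dimensionless, tau_i seconds)
ANNULUS_PRONY = {
    "C3-C5": tuple(zip((0.7440, 0.1098, 0.0356, 0.0251, 0.0855),
                       (0.001, 0.01, 0.1, 1.0, 1000.0))),
    "C5-T1": tuple(zip((0.7440, 0.1098, 0.1580, 0.0251, 0.1053),
                       (0.001, 0.01, 0.1, 1.0, 1000.0))),
}

#: disk nucleus: bulk modulus (MPa), Poisson ratio, viscosity coefficient
NUCLEUS_PROPERTIES = (2.19, 0.49, 0.3)

#: mean annulus bulk modulus (MPa); treated as lognormal in the UQ module
DISK_BULK_MODULUS_MPA = 10.99


class InterferenceError(RuntimeError):
    """Facet surfaces interfere (intersect) at the requested configuration."""


@dataclass
class ClosedCurve:
    """A periodic parametric curve through ordered 3D control points.

    ``__call__(t)`` evaluates the periodic cubic interpolant at parameter
    t ∈ [0, 1) (values outside are wrapped); the curve passes through
    every control point and closes on itself.
    """

    control_points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points, float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
            raise ValueError("control_points must be (>=3, 3)")
        self.control_points = pts
        closed = np.vstack([pts, pts[:1]])
        # chord-length parameterization normalized to [0, 1]
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("repeated consecutive control points")
        t = np.concatenate([[0.0], np.cumsum(seg)])
        self._t = t / t[-1]
        self._spline = CubicSpline(self._t, closed, bc_type="periodic")

    def __call__(self, t) -> np.ndarray:
        return self._spline(np.mod(t, 1.0))

    def sample(self, n: int = 256) -> np.ndarray:
        return self(np.linspace(0.0, 1.0, n, endpoint=False))

    def centroid(self, n: int = 1024) -> np.ndarray:
        """Arc-length-weighted centroid of the curve."""
        t = np.linspace(0.0, 1.0, n + 1)
        p = self(t)
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        mid = 0.5 * (p[:-1] + p[1:])
        return (mid * seg[:, None]).sum(axis=0) / seg.sum()


@dataclass
class LigamentSpec:
    """One ligament (or joint capsule) modeled as discrete spring elements.

    ``spring_pairs`` are (node_on_upper, node_on_lower) index pairs;
    ``load_curve`` is the force-displacement table (displacement mm,
    force N) applied to each spring after multiplying forces by
    ``scale_factor``; ``rest_lengths`` (mm) come from the individual's
    geometry.
    """

    kind: str
    level_group: str
    spring_pairs: list
    load_curve: np.ndarray
    scale_factor: float
    rest_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in LIGAMENT_KINDS:
            raise ValueError(f"unknown ligament kind {self.kind!r}")
        if self.level_group not in LEVEL_GROUPS:
            raise ValueError(f"unknown level group {self.level_group!r}")
        self.load_curve = np.asarray(self.load_curve, float)
        if self.load_curve.ndim != 2 or self.load_curve.shape[1] != 2:
            raise ValueError("load_curve must be (n, 2): displacement mm, force N")
        d, f = self.load_curve[:, 0], self.load_curve[:, 1]
        if np.any(np.diff(d) <= 0):
            raise ValueError("load-curve displacements must strictly increase")
        if np.any(f < 0):
            raise ValueError("load-curve forces must be nonnegative")
        if not self.scale_factor > 0:
            raise ValueError("scale_factor must be > 0")
        if self.rest_lengths is not None:
            self.rest_lengths = np.asarray(self.rest_lengths, float)


@dataclass
class MaterialSpec:
    """Disk material record: annulus viscoelasticity and fluid nucleus."""

    annulus_bulk_modulus: float
    annulus_prony: tuple
    nucleus_bulk_modulus: float
    nucleus_poisson: float
    nucleus_viscosity_coefficient: float

    def __post_init__(self) -> None:
        if self.annulus_bulk_modulus <= 0 or self.nucleus_bulk_modulus <= 0:
            raise ValueError("bulk moduli must be positive")
        if not 0 < self.nucleus_poisson <= 0.5:
            raise ValueError("Poisson ratio must be in (0, 0.5]")
        taus = [tau for _, tau in self.annulus_prony]
        if np.any(np.diff(taus) <= 0):
            raise ValueError("Prony relaxation times must strictly increase")


def default_material_spec(level_group: str = "C3-C5") -> MaterialSpec:
    """Disk material record at the tabulated values for one level group."""
    if level_group not in LEVEL_GROUPS:
        raise ValueError(f"unknown level group {level_group!r}")
    k, nu, eta = NUCLEUS_PROPERTIES
    return MaterialSpec(
        annulus_bulk_modulus=DISK_BULK_MODULUS_MPA,
        annulus_prony=ANNULUS_PRONY[level_group],
        nucleus_bulk_modulus=k,
        nucleus_poisson=nu,
        nucleus_viscosity_coefficient=eta,
    )


# ---------------------------------------------------------------------------
# disk boundary curves and nucleus/annulus interface
# ---------------------------------------------------------------------------


def _best_fit_plane(points: np.ndarray):
    """Centroid and orthonormal (u, v, normal) axes of the best-fit plane."""
    c = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, vt[0], vt[1], vt[2], s


def fit_boundary_curve(endplate_vertices: np.ndarray) -> ClosedCurve:
    """Fit a closed periodic cubic through a loop of endplate vertices.

    Points may arrive in any order: they are canonically re-ordered by
    angle about their centroid in the best-fit plane before fitting, so
    permuted input yields the same curve geometry.
    """
    pts = np.asarray(endplate_vertices, float)
    pts = np.unique(pts, axis=0) if len(pts) else pts
    if len(pts) < 4:
        raise ValueError("need at least 4 distinct points")
    c, u, v, _, s = _best_fit_plane(pts)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise ValueError("points are collinear; no boundary plane defined")
    ang = np.arctan2((pts - c) @ v, (pts - c) @ u)
    order = np.argsort(ang)
    ordered = pts[order]
    # canonical start: smallest angle; direction: increasing angle
    return ClosedCurve(control_points=ordered)


def nucleus_ellipse(boundary: ClosedCurve, proportion: float, n_points: int = 64) -> ClosedCurve:
    """Ellipse marking the nucleus/annulus interface inside a disk boundary.

    Centered at the boundary centroid, lying in the boundary's best-fit
    plane, oriented along the boundary's in-plane principal axes, with
    semi-axes equal to ``proportion`` times the boundary's principal
    half-extents.
    """
    if not 0 < proportion < 1:
        raise ValueError("proportion must lie in (0, 1)")
    samples = boundary.sample(1024)
    center = boundary.centroid()
    d = samples - center
    _, u, v, _, _ = _best_fit_plane(samples)
    xy = np.column_stack([d @ u, d @ v])
    # in-plane principal directions of the boundary
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)
    a_dir, b_dir = evecs[:, 1], evecs[:, 0]  # major, minor
    half_a = np.abs(xy @ a_dir).max()
    half_b = np.abs(xy @ b_dir).max()
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    axis_a = u * a_dir[0] + v * a_dir[1]
    axis_b = u * b_dir[0] + v * b_dir[1]
    pts = (
        center
        + np.outer(np.cos(theta), proportion * half_a * axis_a)
        + np.outer(np.sin(theta), proportion * half_b * axis_b)
    )
    return ClosedCurve(control_points=pts)


# ---------------------------------------------------------------------------
# facet cartilage extrusion
# ---------------------------------------------------------------------------


def _vertex_normals(patch: TriangleSurface) -> np.ndarray:
    """Area-weighted vertex normals of a (possibly open) patch."""
    v, f = patch.vertices, patch.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


def _orient_towards(normals: np.ndarray, patch: TriangleSurface, other: TriangleSurface) -> np.ndarray:
    """Flip the whole normal field if it points away from the other patch."""
    direction = other.vertices.mean(axis=0) - patch.vertices.mean(axis=0)
    if np.mean(normals @ direction) < 0:
        return -normals
    return normals


def _wedge_shell(patch: TriangleSurface, normals: np.ndarray, t: float) -> np.ndarray:
    """Boundary triangles (K,3,3) of the wedge layer of thickness t."""
    v = patch.vertices
    top = v + t * normals
    f = patch.faces
    tris = [v[f][:, ::-1, :], top[f]]  # bottom (reversed) and top
    for e0, e1 in open_boundary_edges(f):
        quad = np.array([v[e0], v[e1], top[e1], top[e0]])
        tris.append(quad[None, [0, 1, 2]])
        tris.append(quad[None, [0, 2, 3]])
    return np.concatenate(tris, axis=0)


def facet_cartilage_thickness(
    patch_a: TriangleSurface,
    patch_b: TriangleSurface,
    search_tolerance: float = 0.01,
) -> tuple[float, TriangleSurface, TriangleSurface]:
    """Maximal non-interfering constant cartilage thickness for a facet joint.

    Both patches are extruded by the same thickness t along outward vertex
    normals (oriented toward the opposing patch).  Returns the largest t,
    found by bisection to ``search_tolerance`` mm, for which the two wedge
    layers do not intersect (triangle-triangle tests), together with the
    two extruded layer shells at that thickness.
    """
    if search_tolerance <= 0:
        raise ValueError("search_tolerance must be positive")
    na = _orient_towards(_vertex_normals(patch_a), patch_a, patch_b)
    nb = _orient_towards(_vertex_normals(patch_b), patch_b, patch_a)

    def intersects(t: float) -> bool:
        return any_triangles_intersect(
            _wedge_shell(patch_a, na, t), _wedge_shell(patch_b, nb, t)
        )

    if any_triangles_intersect(
        patch_a.vertices[patch_a.faces], patch_b.vertices[patch_b.faces]
    ):
        raise InterferenceError("interference at zero thickness")

    scale = float(
        np.linalg.norm(
            np.ptp(np.vstack([patch_a.vertices, patch_b.vertices]), axis=0)
        )
    )
    lo, hi = 0.0, search_tolerance
    while not intersects(hi):
        lo = hi
        hi *= 2.0
        if hi > 100.0 * max(scale, 1.0):
            raise InterferenceError(
                "no interference found at any thickness; patches never meet"
            )
    while hi - lo > search_tolerance:
        mid = 0.5 * (lo + hi)
        if intersects(mid):
            hi = mid
        else:
            lo = mid
    t = lo  # largest thickness verified interference-free
    layer_a = _shell_surface(_wedge_shell(patch_a, na, t), patch_a.label)
    layer_b = _shell_surface(_wedge_shell(patch_b, nb, t), patch_b.label)
    if any_triangles_intersect(
        layer_a.vertices[layer_a.faces], layer_b.vertices[layer_b.faces]
    ):
        raise InterferenceError("post-check failed: layers intersect at returned t")
    return float(t), layer_a, layer_b


def _shell_surface(tris: np.ndarray, label: str) -> TriangleSurface:
    verts = tris.reshape(-1, 3)
    faces = np.arange(len(verts)).reshape(-1, 3)
    from .meshes import _merge_vertices

    v, f = _merge_vertices(verts, faces, 1e-9)
    return TriangleSurface(vertices=v, faces=f, label=f"{label}_cartilage")


# ---------------------------------------------------------------------------
# ligaments
# ---------------------------------------------------------------------------

#: mean Table-style scale factors per (kind, level group); ITL has no
#: tabulated factor and must be user-supplied.
DEFAULT_SCALE_FACTORS = {
    ("ALL", "C3-C5"): 0.2500,
    ("ALL", "C5-T1"): 0.2500,
    ("PLL", "C3-C5"): 0.2500,
    ("PLL", "C5-T1"): 0.2500,
    ("ISL", "C3-C5"): 0.2500,
    ("ISL", "C5-T1"): 0.2000,
    ("LF", "C3-C5"): 0.1250,
    ("LF", "C5-T1"): 0.1250,
    ("JC", "C3-C5"): 0.1250,
    ("JC", "C5-T1"): 0.1250,
}


def synthetic_load_curve(
    kind: str, toe_displacement: float = 1.0, stiffness: float = 30.0, n: int = 21
) -> np.ndarray:
    """SYNTHETIC placeholder ligament force-displacement curve (toe + linear).

    The experimentally derived quasi-static ligament curves are not
    tabulated in any machine-readable source, so this generates a generic
    toe region (quadratic up to ``toe_displacement`` mm) followed by a
    linear region of slope ``stiffness`` N/mm.  Intended for tests and
    demonstrations; supply measured curves (CSV: displacement_mm, force_N)
    for real analyses.
    """
    if kind not in LIGAMENT_KINDS:
        raise ValueError(f"unknown ligament kind {kind!r}")
    d = np.linspace(0.0, 3.0 * toe_displacement, n)
    toe = stiffness * d**2 / (2.0 * toe_displacement)
    lin = stiffness * (d - toe_displacement / 2.0)
    f = np.where(d <= toe_displacement, toe, lin)
    return np.column_stack([d, f])


def scale_load_curve(curve: np.ndarray, scale_factor: float) -> np.ndarray:
    """Multiply forces by ``scale_factor`` (displacements unchanged).

    Distributes a whole-ligament response over multiple discrete springs:
    e.g. four springs at factor 0.25 superpose to the original curve.
    """
    if not scale_factor > 0:
        raise ValueError("scale_factor must be > 0")
    curve = np.asarray(curve, float)
    out = curve.copy()
    out[:, 1] = curve[:, 1] * scale_factor
    return out


def attach_ligaments(
    template_attachments: dict,
    shape_set: CorrespondedShapeSet,
    level_group: str = "C3-C5",
    load_curves: dict | None = None,
    scale_factors: dict | None = None,
) -> list:
    """Instantiate ligament springs on every individual of a corresponded set.

    ``template_attachments`` maps ligament kind → list of (upper, lower)
    node-id pairs defined once on the average mesh; correspondence makes
    the same ids valid on every individual.  Returns one list of
    :class:`LigamentSpec` per individual, with per-individual spring rest
    lengths computed from that individual's geometry.
    """
    load_curves = load_curves or {}
    scale_factors = scale_factors or {}
    J = shape_set.J
    for kind, pairs in template_attachments.items():
        if kind not in LIGAMENT_KINDS:
            raise ValueError(f"unknown ligament kind {kind!r}")
        for idx, (a, b) in enumerate(pairs):
            if not (0 <= a < J and 0 <= b < J):
                raise ValueError(
                    f"invalid node id in {kind} pair {idx}: ({a}, {b}) for J={J}"
                )
    out = []
    for i in range(shape_set.n):
        verts = shape_set.shapes[i]
        specs = []
        for kind, pairs in template_attachments.items():
            pairs_arr = np.asarray(pairs, dtype=np.int64)
            rest = np.linalg.norm(
                verts[pairs_arr[:, 0]] - verts[pairs_arr[:, 1]], axis=1
            )
            sf = scale_factors.get(kind, DEFAULT_SCALE_FACTORS.get((kind, level_group)))
            if sf is None:
                raise ValueError(
                    f"no scale factor tabulated for {kind}; supply one explicitly"
                )
            curve = load_curves.get(kind)
            if curve is None:
                curve = synthetic_load_curve(kind)
            specs.append(
                LigamentSpec(
                    kind=kind,
                    level_group=level_group,
                    spring_pairs=[tuple(p) for p in pairs_arr],
                    load_curve=scale_load_curve(curve, sf),
                    scale_factor=float(sf),
                    rest_lengths=rest,
                )
            )
        out.append(specs)
    return out
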