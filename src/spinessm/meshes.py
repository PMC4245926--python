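"""Mesh containers, file I/O and surface resampling.

All meshes use 0-based indices internally; 1-based formats (node/element
text) are converted at the I/O boundary.  Units are fixed package-wide:
millimeters for coordinates, newton-meters for moments, degrees for
rotations.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleSurface",
    "VolumetricMesh",
    "MeshValidationError",
    "read_surface",
    "write_surface",
    "resample_surface",
    "read_vtk_legacy",
    "write_vtk_legacy",
    "read_node_element_text",
    "write_node_element_text",
    "boundary_faces",
    "surface_distance",
]

#: coordinate tolerance (mm) for merging duplicate STL vertices
STL_MERGE_TOL = 1e-6

FILE_HEADER = "units: mm (coordinates), Nm (moments), deg (rotations)"


class MeshValidationError(ValueError):
    """A mesh violates a structural invariant (bad index, degenerate face...)."""


@dataclass
class TriangleSurface:
    """A triangulated surface: ``vertices`` (J, 3) in mm, ``faces`` (F, 3) 0-based.

    ``label`` is a free-text anatomical identifier such as ``"C4"``.
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshValidationError("vertices must be (J, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshValidationError("faces must be (F, 3)")
        if not np.isfinite(self.vertices).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                bad = np.where(
                    (self.faces < 0) | (self.faces >= len(self.vertices))
                )[0][0]
                raise MeshValidationError(
                    f"face {bad} references vertex outside [0, {len(self.vertices)})"
                )
            degen = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degen.any():
                raise MeshValidationError(
                    f"degenerate face(s) at indices {np.where(degen)[0].tolist()}"
                )

    @property
    def vertex_count(self) -> int:
        return len(self.vertices)

    @property
    def face_count(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    def is_closed(self) -> bool:
        return len(open_boundary_edges(self.faces)) == 0


@dataclass
class VolumetricMesh:
    """A tetrahedral mesh: ``nodes`` (N, 3) mm, ``tets`` (T, 4) 0-based.

    ``surface_node_ids`` lists the node indices on the boundary surface.
    Tets are kept in positive-signed-volume orientation
    (det[b-a, c-a, d-a] > 0); negatively oriented input tets are flipped
    on construction.
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface_node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be (N, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise MeshValidationError("tets must be (T, 4)")
        if len(self.tets) and (
            self.tets.min() < 0 or self.tets.max() >= len(self.nodes)
        ):
            raise MeshValidationError("tet index out of range")
        vols = tet_signed_volumes(self.nodes, self.tets)
        flip = vols < 0
        if flip.any():
            self.tets = self.tets.copy()
            self.tets[flip, 2], self.tets[flip, 3] = (
                self.tets[flip, 3].copy(),
                self.tets[flip, 2].copy(),
            )
            vols = tet_signed_volumes(self.nodes, self.tets)
        if len(self.tets) and (vols <= 0).any():
            raise MeshValidationError(
                f"degenerate tets (zero volume): {np.where(vols <= 0)[0].tolist()}"
            )
        if self.surface_node_ids is None:
            bf = boundary_faces(self.tets)
            self.surface_node_ids = np.unique(bf)
        else:
            self.surface_node_ids = np.asarray(self.surface_node_ids, dtype=np.int64)
            if len(self.surface_node_ids) and (
                self.surface_node_ids.min() < 0
                or self.surface_node_ids.max() >= len(self.nodes)
            ):
                raise MeshValidationError("surface node id out of range")

    @property
    def node_count(self) -> int:
        return len(self.nodes)


def tet_signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tet under the a,b,c,d → det[b-a,c-a,d-a]/6 convention."""
    if len(tets) == 0:
        return np.zeros(0)
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a) / 6.0


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Triangular faces of a tet mesh that belong to exactly one tet."""
    # local faces chosen so each points outward under positive orientation
    local = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    faces = tets[:, local].reshape(-1, 3)
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def open_boundary_edges(faces: np.ndarray) -> np.ndarray:
    """Edges referenced by exactly one face (empty for a closed surface)."""
    if len(faces) == 0:
        return np.zeros((0, 2), dtype=np.int64)
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, counts = np.unique(key, axis=0, return_counts=True)
    return uniq[counts == 1]


# ---------------------------------------------------------------------------
# surface I/O (PLY ascii, STL, OBJ) via trimesh
# ---------------------------------------------------------------------------

_SURFACE_EXT = {".ply": "ply", ".stl": "stl", ".obj": "obj"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in ("ply", "stl", "obj"):
            raise ValueError(f"unsupported surface format {fmt!r}")
        return f
    ext = path.suffix.lower()
    if ext not in _SURFACE_EXT:
        raise ValueError(f"cannot infer surface format from extension {ext!r}")
    return _SURFACE_EXT[ext]


def read_surface(path: str | Path, format: str | None = None) -> TriangleSurface:
    """Read a triangulated surface from PLY (ascii), STL or OBJ.

    Vertex order is preserved as stored in the file.  STL stores an
    unindexed triangle soup, so duplicate vertices are merged at
    ``STL_MERGE_TOL`` mm in first-occurrence order.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        mesh = trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise IOError(f"failed to parse {path} as {fmt}: {exc}") from exc
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = _merge_vertices(vertices, faces, STL_MERGE_TOL)
    return TriangleSurface(vertices=vertices, faces=faces, label=path.stem)


def _merge_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices closer than ``tol``; first occurrence keeps its order."""
    quant = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(
        quant, axis=0, return_index=True, return_inverse=True
    )
    # renumber unique vertices by first appearance, not lexicographic order
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_vertices = vertices[first[order]]
    new_faces = rank[inverse][faces]
    keep = ~(
        (new_faces[:, 0] == new_faces[:, 1])
        | (new_faces[:, 1] == new_faces[:, 2])
        | (new_faces[:, 0] == new_faces[:, 2])
    )
    return new_vertices, new_faces[keep]


def write_surface(
    surface: TriangleSurface, path: str | Path, format: str | None = None
) -> None:
    """Write a surface as ascii PLY, ascii STL or OBJ (inferred from extension)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mesh = surface.to_trimesh()
    if fmt == "ply":
        data = mesh.export(file_type="ply", encoding="ascii")
    elif fmt == "stl":
        data = mesh.export(file_type="stl_ascii")
    else:
        data = mesh.export(file_type="obj")
    if isinstance(data, bytes):
        path.write_bytes(data)
    else:
        path.write_text(data)


# ---------------------------------------------------------------------------
# volumetric I/O: legacy ascii VTK unstructured grid, node/element text
# ---------------------------------------------------------------------------


def write_vtk_legacy(mesh: VolumetricMesh | TriangleSurface, path: str | Path) -> None:
    """Write a legacy ascii VTK unstructured grid (tets) or polydata-style tri grid."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("# vtk DataFile Version 3.0\n")
    buf.write(f"spinessm mesh; {FILE_HEADER}\n")
    buf.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    if isinstance(mesh, VolumetricMesh):
        points, cells, cell_type = mesh.nodes, mesh.tets, 10
    else:
        points, cells, cell_type = mesh.vertices, mesh.faces, 5
    buf.write(f"POINTS {len(points)} double\n")
    for p in points:
        buf.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
    k = cells.shape[1]
    buf.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
    for c in cells:
        buf.write(f"{k} " + " ".join(str(int(i)) for i in c) + "\n")
    buf.write(f"CELL_TYPES {len(cells)}\n")
    buf.writelines(f"{cell_type}\n" for _ in range(len(cells)))
    path.write_text(buf.getvalue())


def read_vtk_legacy(path: str | Path) -> VolumetricMesh | TriangleSurface:
    """Read a legacy ascii VTK unstructured grid of tets (type 10) or tris (type 5)."""
    tokens = Path(path).read_text().split()
    try:
        pi = tokens.index("POINTS")
    except ValueError as exc:
        raise IOError(f"{path}: no POINTS section") from exc
    n_pts = int(tokens[pi + 1])
    coords = np.array(tokens[pi + 3 : pi + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
    ci = tokens.index("CELLS")
    n_cells = int(tokens[ci + 1])
    total = int(tokens[ci + 2])
    raw = np.array(tokens[ci + 3 : ci + 3 + total], dtype=np.int64)
    ti = tokens.index("CELL_TYPES")
    types = np.array(
        tokens[ti + 2 : ti + 2 + n_cells], dtype=np.int64
    )
    cells = []
    pos = 0
    for _ in range(n_cells):
        k = raw[pos]
        cells.append(raw[pos + 1 : pos + 1 + k])
        pos += k + 1
    if (types == 10).all():
        return VolumetricMesh(nodes=coords, tets=np.vstack(cells))
    if (types == 5).all():
        return TriangleSurface(vertices=coords, faces=np.vstack(cells))
    raise IOError(f"{path}: unsupported mix of VTK cell types {np.unique(types)}")


def write_node_element_text(mesh: VolumetricMesh, path: str | Path) -> None:
    """Write the plain node/element text format (1-based ids).

    Layout: a ``*NODES`` block of ``id x y z`` lines then an ``*ELEMENTS``
    block of ``id n1 n2 n3 n4`` lines; ids are 1-based in the file.
    """
    with open(path, "w") as fh:
        fh.write(f"# {FILE_HEADER}\n*NODES\n")
        for i, p in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write("*ELEMENTS\n")
        for i, t in enumerate(mesh.tets, start=1):
            fh.write(f"{i} {t[0] + 1} {t[1] + 1} {t[2] + 1} {t[3] + 1}\n")


def read_node_element_text(path: str | Path) -> VolumetricMesh:
    """Read the plain node/element text format (1-based ids in the file)."""
    nodes: list[list[float]] = []
    tets: list[list[int]] = []
    section = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.upper().startswith("*NODES"):
            section = "nodes"
            continue
        if line.upper().startswith("*ELEMENTS"):
            section = "elements"
            continue
        parts = line.split()
        if section == "nodes":
            nodes.append([float(x) for x in parts[1:4]])
        elif section == "elements":
            tets.append([int(x) - 1 for x in parts[1:5]])
        else:
            raise IOError(f"{path}: data before any *NODES/*ELEMENTS header")
    return VolumetricMesh(nodes=np.array(nodes), tets=np.array(tets, dtype=np.int64))


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def surface_distance(
    a: TriangleSurface, b: TriangleSurface, samples: int = 2000, seed: int = 0
) -> float:
    """Approximate symmetric Hausdorff distance (mm) via point sampling."""
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)

    def cloud(s: TriangleSurface) -> np.ndarray:
        pts, _ = trimesh.sample.sample_surface(s.to_trimesh(), samples, seed=rng)
        return np.vstack([s.vertices, pts])

    ca, cb = cloud(a), cloud(b)
    d_ab = cKDTree(cb).query(ca)[0].max()
    d_ba = cKDTree(ca).query(cb)[0].max()
    return float(max(d_ab, d_ba))


def resample_surface(
    surface: TriangleSurface,
    target_faces: int,
    tolerance: float | None = None,
) -> TriangleSurface:
    """Resample a closed surface to approximately ``target_faces`` triangles.

    Decimation collapses shortest edges (midpoint placement) subject to a
    manifold link condition; if the surface has fewer faces than requested
    it is loop-subdivided first.  The result stays closed and, when
    ``tolerance`` (mm) is given, within that symmetric Hausdorff distance
    of the input.
    """
    if target_faces < 4:
        raise ValueError("target_faces must be >= 4")
    boundary = open_boundary_edges(surface.faces)
    if len(boundary):
        raise MeshValidationError(
            f"surface is open: {len(boundary)} boundary edges, e.g. "
            f"{boundary[: min(5, len(boundary))].tolist()}"
        )
    vertices, faces = surface.vertices, surface.faces
    while len(faces) < target_faces * 0.9:
        vertices, faces = trimesh.remesh.subdivide(vertices, faces)
    if len(faces) > target_faces:
        vertices, faces = _decimate(vertices, faces, target_faces)
    out = TriangleSurface(vertices=vertices, faces=faces, label=surface.label)
    if not (0.9 * target_faces <= out.face_count <= 1.1 * target_faces):
        raise MeshValidationError(
            f"could not reach {target_faces} faces (got {out.face_count})"
        )
    if tolerance is not None:
        d = surface_distance(surface, out)
        if d > tolerance:
            raise MeshValidationError(
                f"resampled surface deviates {d:.4g} mm > tolerance {tolerance}"
            )
    return out


def _decimate(
    vertices: np.ndarray, faces: np.ndarray, target_faces: int
) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-edge-collapse decimation of a closed manifold triangulation."""
    import heapq

    verts = vertices.copy()
    face_list = faces.copy()
    alive_face = np.ones(len(face_list), dtype=bool)
    # adjacency: vertex -> set of face ids
    v_faces: list[set[int]] = [set() for _ in range(len(verts))]
    for fi, f in enumerate(face_list):
        for v in f:
            v_faces[v].add(fi)

    def neighbors(v: int) -> set[int]:
        out: set[int] = set()
        for fi in v_faces[v]:
            out.update(face_list[fi])
        out.discard(v)
        return out

    def edge_key(u: int, v: int) -> tuple[int, int]:
        return (u, v) if u < v else (v, u)

    heap: list[tuple[float, int, int]] = []
    seen: set[tuple[int, int]] = set()
    for f in face_list:
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            k = edge_key(int(u), int(v))
            if k not in seen:
                seen.add(k)
                heapq.heappush(
                    heap, (float(np.linalg.norm(verts[k[0]] - verts[k[1]])), *k)
                )

    n_alive = int(alive_face.sum())
    while n_alive > target_faces and heap:
        _, u, v = heapq.heappop(heap)
        if not v_faces[u] or not v_faces[v]:
            continue  # vertex already removed
        shared = v_faces[u] & v_faces[v]
        if len(shared) != 2:
            continue  # edge no longer exists or non-manifold
        # link condition: common vertex neighbors must be exactly the two
        # faces' apex vertices, else the collapse pinches the surface
        common = neighbors(u) & neighbors(v)
        apex = set()
        for fi in shared:
            apex.update(face_list[fi])
        apex -= {u, v}
        if common != apex or len(apex) != 2:
            continue
        mid = 0.5 * (verts[u] + verts[v])
        # reject collapses that flip any surviving face normal
        ok = True
        moved = (v_faces[u] | v_faces[v]) - shared
        for fi in moved:
            f = face_list[fi]
            old = np.cross(
                verts[f[1]] - verts[f[0]], verts[f[2]] - verts[f[0]]
            )
            g = [mid if x in (u, v) else verts[x] for x in f]
            new = np.cross(g[1] - g[0], g[2] - g[0])
            if np.dot(old, new) <= 1e-12 * np.dot(old, old):
                ok = False
                break
        if not ok:
            continue
        # perform collapse: v absorbs u at the midpoint
        verts[v] = mid
        for fi in shared:
            alive_face[fi] = False
            for x in face_list[fi]:
                v_faces[x].discard(fi)
            n_alive -= 1
        for fi in list(v_faces[u]):
            f = face_list[fi]
            face_list[fi] = np.where(f == u, v, f)
            v_faces[v].add(fi)
        v_faces[u] = set()
        # refresh edge lengths around v
        for w in neighbors(v):
            k = edge_key(v, int(w))
            heapq.heappush(
                heap, (float(np.linalg.norm(verts[k[0]] - verts[k[1]])), *k)
            )

    kept = face_list[alive_face]
    used = np.unique(kept)
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[kept]
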