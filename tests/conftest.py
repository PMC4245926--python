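import numpy as np
import pytest
import trimesh

from spinessm import TriangleSurface, VolumetricMesh


@pytest.fixture
def icosphere_1280() -> TriangleSurface:
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriangleSurface(
        vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces), label="sphere"
    )


@pytest.fixture
def tetra_surface() -> TriangleSurface:
    """Minimal closed surface: a single tetrahedron."""
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return TriangleSurface(vertices=v, faces=f, label="tet")


@pytest.fixture
def random_tet_mesh() -> VolumetricMesh:
    """A Delaunay tet mesh of random points in a box (mm scale)."""
    from scipy.spatial import Delaunay

    rng = np.random.default_rng(42)
    pts = rng.uniform(-1.0, 1.0, (80, 3)) * np.array([10.0, 8.0, 6.0])
    return VolumetricMesh(nodes=pts, tets=Delaunay(pts).simplices)


@pytest.fixture
def square_patch():
    """Open planar patch in the z=0 plane, 10x10 mm."""
    v = np.array([[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0]], float)
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return TriangleSurface(vertices=v, faces=f, label="patch")
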