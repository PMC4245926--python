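import numpy as np
import pytest
from scipy.spatial import cKDTree

from spinessm import (
    CorrespondedShapeSet,
    CPDParams,
    TriangleSurface,
    VolumetricMesh,
    average_shape,
    build_corresponded_set,
    center_spine,
    register_nonrigid,
    warp_volumetric_mesh,
)
from spinessm.correspondence import (
    RegistrationError,
    load_corresponded_set,
    save_corresponded_set,
)
from spinessm.meshes import MeshValidationError
from spinessm.synthetic import make_vertebra_surface


@pytest.fixture(scope="module")
def vertebra():
    return make_vertebra_surface(resolution=2)


class TestRegisterNonrigid:
    def test_identity_target_gives_zero_displacement(self, vertebra):
        out = register_nonrigid(vertebra, vertebra)
        assert np.abs(out - vertebra.vertices).max() < 1e-6

    def test_pure_translation_recovered(self, vertebra):
        shifted = TriangleSurface(vertebra.vertices + [5.0, 0.0, 0.0], vertebra.faces)
        out = register_nonrigid(vertebra, shifted)
        assert np.abs(out - shifted.vertices).max() < 0.1

    def test_translation_preserves_intervertex_distances(self, vertebra):
        shifted = TriangleSurface(vertebra.vertices + [5.0, 0.0, 0.0], vertebra.faces)
        out = register_nonrigid(vertebra, shifted)
        idx = np.arange(0, vertebra.vertex_count, 7)
        d_in = np.linalg.norm(vertebra.vertices[idx][:, None] - vertebra.vertices[idx][None], axis=2)
        d_out = np.linalg.norm(out[idx][:, None] - out[idx][None], axis=2)
        assert np.abs(d_in - d_out).max() < 0.1

    def test_smooth_radial_bump_recovered(self, vertebra):
        v = vertebra.vertices
        c = v.mean(axis=0)
        d = v - c
        r = np.linalg.norm(d, axis=1, keepdims=True)
        unit = d / r
        axis = np.array([1.0, 0.0, 0.0])
        ang = np.arccos(np.clip(unit @ axis, -1, 1))
        bump = 2.0 * np.exp(-((ang / 0.5) ** 2))
        target = TriangleSurface(v + unit * bump[:, None], vertebra.faces)
        out = register_nonrigid(vertebra, target)
        mean_dist = cKDTree(target.vertices).query(out)[0].mean()
        assert mean_dist < 0.2

    def test_too_few_vertices_rejected(self):
        tri = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], float)
        with pytest.raises(ValueError, match="10 vertices"):
            register_nonrigid(tri, tri)

    def test_unreachable_tolerance_raises_with_residual(self, vertebra):
        far = TriangleSurface(vertebra.vertices * 3.0 + 100.0, vertebra.faces)
        params = CPDParams(max_iterations=2, tolerance=1e-9)
        with pytest.raises(RegistrationError):
            register_nonrigid(vertebra, far, params)


class TestBuildCorrespondedSet:
    def test_identical_copies_give_identical_shapes(self, vertebra):
        out = build_corresponded_set([vertebra] * 3, template_index=0)
        assert out.n == 3 and out.J == vertebra.vertex_count
        for i in range(3):
            assert np.abs(out.shapes[i] - vertebra.vertices).max() < 1e-6

    def test_template_entry_is_verbatim(self, vertebra):
        others = [
            TriangleSurface(vertebra.vertices + [1.0, 0, 0], vertebra.faces),
            TriangleSurface(vertebra.vertices + [0, 1.0, 0], vertebra.faces),
        ]
        out = build_corresponded_set([vertebra] + others, template_index=0)
        assert np.array_equal(out.shapes[0], vertebra.vertices)
        assert np.array_equal(out.faces, vertebra.faces)

    def test_translated_family_recovered(self, vertebra):
        shifts = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [2, -2, 1]], float
        )
        surfaces = [
            TriangleSurface(vertebra.vertices + s, vertebra.faces) for s in shifts
        ]
        out = build_corresponded_set(surfaces, template_index=0)
        for i, s in enumerate(shifts):
            assert np.abs(out.shapes[i] - (vertebra.vertices + s)).max() < 0.1

    def test_bad_template_index(self, vertebra):
        with pytest.raises(IndexError):
            build_corresponded_set([vertebra, vertebra], template_index=5)

    def test_set_requires_two_shapes(self, vertebra):
        with pytest.raises(MeshValidationError, match="n >= 2"):
            CorrespondedShapeSet(
                shapes=vertebra.vertices[None], faces=vertebra.faces
            )

    def test_save_load_round_trip(self, tmp_path, vertebra):
        out = build_corresponded_set([vertebra] * 2, template_index=0)
        save_corresponded_set(out, tmp_path / "set")
        back = load_corresponded_set(tmp_path / "set")
        np.testing.assert_allclose(back.shapes, out.shapes, atol=1e-6)
        np.testing.assert_array_equal(back.faces, out.faces)


class TestAverageShape:
    def test_identical_shapes_average_to_themselves(self, vertebra):
        ss = CorrespondedShapeSet(
            shapes=np.stack([vertebra.vertices] * 4), faces=vertebra.faces
        )
        np.testing.assert_array_equal(average_shape(ss), vertebra.vertices)

    def test_antisymmetric_pair_averages_to_zero(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(20, 3))
        ss = CorrespondedShapeSet(shapes=np.stack([p, -p]), faces=np.zeros((0, 3), int))
        np.testing.assert_allclose(average_shape(ss), 0.0, atol=1e-15)

    def test_matches_independent_summation(self):
        rng = np.random.default_rng(1)
        shapes = rng.normal(size=(3, 15, 3))
        ss = CorrespondedShapeSet(shapes=shapes, faces=np.zeros((0, 3), int))
        # independent oracle: explicit per-vertex accumulation
        acc = np.zeros((15, 3))
        for s in shapes:
            acc += s
        np.testing.assert_allclose(average_shape(ss), acc / 3.0, atol=1e-12)


class TestWarpVolumetricMesh:
    def test_zero_displacement_is_identity(self, random_tet_mesh):
        disp = np.zeros((len(random_tet_mesh.surface_node_ids), 3))
        out = warp_volumetric_mesh(random_tet_mesh, disp)
        np.testing.assert_array_equal(out.nodes, random_tet_mesh.nodes)
        np.testing.assert_array_equal(out.tets, random_tet_mesh.tets)

    def test_uniform_translation_moves_interior_exactly(self, random_tet_mesh):
        t = np.array([2.0, -1.0, 3.0])
        disp = np.tile(t, (len(random_tet_mesh.surface_node_ids), 1))
        out = warp_volumetric_mesh(random_tet_mesh, disp)
        np.testing.assert_allclose(out.nodes, random_tet_mesh.nodes + t, atol=1e-6)

    def test_affine_field_reproduced_in_interior(self, random_tet_mesh):
        A = np.array([[1.05, 0.02, 0.0], [0.0, 0.98, 0.03], [0.01, 0.0, 1.1]])
        b = np.array([2.0, -1.0, 3.0])
        sid = random_tet_mesh.surface_node_ids
        disp = random_tet_mesh.nodes[sid] @ A.T + b - random_tet_mesh.nodes[sid]
        out = warp_volumetric_mesh(random_tet_mesh, disp)
        target = random_tet_mesh.nodes @ A.T + b
        assert np.abs(out.nodes - target).max() < 1e-6

    def test_inverting_warp_raises_listing_elements(self, random_tet_mesh):
        sid = random_tet_mesh.surface_node_ids
        # collapse the whole boundary to a point: guaranteed inversion
        disp = -random_tet_mesh.nodes[sid]
        with pytest.raises(MeshValidationError, match="inverted"):
            warp_volumetric_mesh(random_tet_mesh, disp)

    def test_wrong_displacement_shape_rejected(self, random_tet_mesh):
        with pytest.raises(ValueError, match="shape"):
            warp_volumetric_mesh(random_tet_mesh, np.zeros((3, 3)))


class TestCenterSpine:
    def test_centroid_of_central_component_is_origin(self, random_tet_mesh):
        rng = np.random.default_rng(3)
        spine = [
            VolumetricMesh(
                nodes=random_tet_mesh.nodes + rng.uniform(-20, 20, 3),
                tets=random_tet_mesh.tets,
            )
            for _ in range(3)
        ]
        out = center_spine(spine, 1)
        assert np.abs(out[1].nodes.mean(axis=0)).max() < 1e-9

    def test_relative_positions_preserved(self, random_tet_mesh):
        a = random_tet_mesh.nodes
        spine = [a, a + [0.0, 25.0, 0.0]]
        out = center_spine(spine, 0)
        np.testing.assert_allclose(out[1] - out[0], spine[1] - spine[0], atol=1e-12)

    def test_translation_invariance(self, random_tet_mesh):
        a = random_tet_mesh.nodes
        spine = [a, a + [0.0, 25.0, 0.0]]
        shifted = [c + [10.0, 10.0, 10.0] for c in spine]
        out0 = center_spine(spine, 0)
        out1 = center_spine(shifted, 0)
        for c0, c1 in zip(out0, out1):
            np.testing.assert_allclose(c0, c1, atol=1e-12)

    def test_already_centered_unchanged(self):
        a = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        out = center_spine([a], 0)
        np.testing.assert_allclose(out[0], a, atol=1e-15)
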