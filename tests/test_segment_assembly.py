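import numpy as np
import pytest

from spinessm import TriangleSurface
from spinessm.correspondence import CorrespondedShapeSet
from spinessm.segment_assembly import (
    ANNULUS_PRONY,
    InterferenceError,
    LigamentSpec,
    MaterialSpec,
    attach_ligaments,
    default_material_spec,
    facet_cartilage_thickness,
    fit_boundary_curve,
    nucleus_ellipse,
    scale_load_curve,
    synthetic_load_curve,
)


def _circle_points(radius, n=8, center=(0, 0, 0), seed=None):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [radius * np.cos(th), radius * np.sin(th), np.zeros(n)]
    ) + np.asarray(center, float)
    if seed is not None:
        pts = pts[np.random.default_rng(seed).permutation(n)]
    return pts


class TestBoundaryCurve:
    def test_circle_radius_preserved(self):
        curve = fit_boundary_curve(_circle_points(10.0, 8))
        r = np.linalg.norm(curve.sample(400), axis=1)
        assert np.abs(r - 10.0).max() < 0.05

    def test_curve_is_closed(self):
        curve = fit_boundary_curve(_circle_points(10.0, 8))
        assert np.linalg.norm(curve(0.0) - curve(1.0 - 1e-12)) < 1e-6

    def test_interpolates_every_input_point(self):
        pts = _circle_points(7.0, 12)
        curve = fit_boundary_curve(pts)
        samples = curve.sample(4000)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(samples).query(pts)
        assert d.max() < 1e-2  # dense sampling resolution

    def test_permuted_points_give_same_geometry(self):
        pts = _circle_points(5.0, 10)
        c1 = fit_boundary_curve(pts)
        c2 = fit_boundary_curve(pts[np.random.default_rng(3).permutation(10)])
        t = np.linspace(0, 1, 200, endpoint=False)
        np.testing.assert_allclose(c1(t), c2(t), atol=1e-9)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            fit_boundary_curve(pts)


class TestNucleusEllipse:
    def test_circular_boundary_scales_to_half_radius(self):
        boundary = fit_boundary_curve(_circle_points(10.0, 16))
        ell = nucleus_ellipse(boundary, 0.5)
        r = np.linalg.norm(ell.sample(200) - boundary.centroid(), axis=1)
        assert np.abs(r - 5.0).max() < 0.1

    def test_centroid_matches_boundary_centroid(self):
        pts = _circle_points(8.0, 12, center=(3.0, -2.0, 5.0))
        boundary = fit_boundary_curve(pts)
        ell = nucleus_ellipse(boundary, 0.4)
        assert np.linalg.norm(ell.centroid() - boundary.centroid()) < 1e-6

    def test_elliptical_boundary_principal_half_extents(self):
        th = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack([10 * np.cos(th), 6 * np.sin(th), np.zeros(24)])
        boundary = fit_boundary_curve(pts)
        ell = nucleus_ellipse(boundary, 0.5)
        xy = ell.sample(2000)
        # oracle: half-extents of the returned curve along the boundary axes
        d = xy - xy.mean(axis=0)
        assert abs(np.abs(d[:, 0]).max() - 5.0) / 5.0 < 0.02
        assert abs(np.abs(d[:, 1]).max() - 3.0) / 3.0 < 0.02

    def test_proportion_near_one_approaches_boundary(self):
        boundary = fit_boundary_curve(_circle_points(10.0, 16))
        ell = nucleus_ellipse(boundary, 0.999)
        r = np.linalg.norm(ell.sample(200) - boundary.centroid(), axis=1)
        assert np.abs(r - 10.0).max() < 0.15

    def test_proportion_out_of_range(self):
        boundary = fit_boundary_curve(_circle_points(10.0, 8))
        for bad in (0.0, 1.0, -0.3, 2.0):
            with pytest.raises(ValueError):
                nucleus_ellipse(boundary, bad)


def _unit(v):
    return v / np.linalg.norm(v)


class TestFacetCartilage:
    def test_parallel_planes_split_gap_evenly(self, square_patch):
        other = TriangleSurface(
            square_patch.vertices + [0.0, 0.0, 2.0],
            square_patch.faces[:, ::-1],  # normals face downward
        )
        t, layer_a, layer_b = facet_cartilage_thickness(square_patch, other, 0.01)
        assert abs(t - 1.0) <= 0.011
        assert layer_a.is_closed() and layer_b.is_closed()

    def test_coincident_patches_fail(self, square_patch):
        with pytest.raises(InterferenceError, match="zero thickness"):
            facet_cartilage_thickness(square_patch, square_patch, 0.01)

    def test_tilted_patches_match_grid_search_oracle(self, square_patch):
        # opposing patch tilted so the gap runs from 1 mm to 3 mm
        v = square_patch.vertices.copy()
        v[:, 2] = 1.0 + 2.0 * v[:, 0] / 10.0
        tilted = TriangleSurface(v, square_patch.faces[:, ::-1])
        tol = 0.005
        t, _, _ = facet_cartilage_thickness(square_patch, tilted, tol)

        from spinessm._intersect import any_triangles_intersect
        from spinessm.segment_assembly import (
            _orient_towards,
            _vertex_normals,
            _wedge_shell,
        )

        na = _orient_towards(_vertex_normals(square_patch), square_patch, tilted)
        nb = _orient_towards(_vertex_normals(tilted), tilted, square_patch)
        grid = np.arange(0.0, 2.0, tol / 4)
        free = [
            g
            for g in grid
            if not any_triangles_intersect(
                _wedge_shell(square_patch, na, g), _wedge_shell(tilted, nb, g)
            )
        ]
        assert abs(t - max(free)) <= 2 * tol

    def test_returned_layers_never_intersect(self, square_patch):
        other = TriangleSurface(
            square_patch.vertices + [1.0, 2.0, 3.0], square_patch.faces[:, ::-1]
        )
        from spinessm._intersect import any_triangles_intersect

        t, la, lb = facet_cartilage_thickness(square_patch, other, 0.02)
        assert not any_triangles_intersect(
            la.vertices[la.faces], lb.vertices[lb.faces]
        )


class TestLigaments:
    @pytest.fixture
    def simple_set(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-10, 10, (30, 3))
        return CorrespondedShapeSet(
            shapes=np.stack([base, base, 2.0 * base]), faces=np.zeros((0, 3), int)
        )

    def test_identical_individuals_same_rest_lengths(self, simple_set):
        att = {"ALL": [(0, 1), (2, 3)], "ISL": [(4, 5)]}
        out = attach_ligaments(att, simple_set)
        np.testing.assert_allclose(
            out[0][0].rest_lengths, out[1][0].rest_lengths, atol=1e-12
        )

    def test_similarity_scaling_doubles_rest_lengths(self, simple_set):
        att = {"PLL": [(0, 1), (2, 3), (6, 7)]}
        out = attach_ligaments(att, simple_set)
        np.testing.assert_allclose(
            out[2][0].rest_lengths, 2.0 * out[0][0].rest_lengths, rtol=1e-12
        )

    def test_pair_counts_preserved_per_kind(self, simple_set):
        att = {"ALL": [(0, 1), (2, 3)], "LF": [(4, 5), (6, 7), (8, 9)]}
        out = attach_ligaments(att, simple_set)
        for specs in out:
            counts = {s.kind: len(s.spring_pairs) for s in specs}
            assert counts == {"ALL": 2, "LF": 3}

    def test_invalid_node_id_reports_kind_and_pair(self, simple_set):
        with pytest.raises(ValueError, match="JC pair 1"):
            attach_ligaments({"JC": [(0, 1), (0, 99)]}, simple_set)

    def test_itl_requires_explicit_scale_factor(self, simple_set):
        with pytest.raises(ValueError, match="ITL"):
            attach_ligaments({"ITL": [(0, 1)]}, simple_set)
        out = attach_ligaments(
            {"ITL": [(0, 1)]}, simple_set, scale_factors={"ITL": 0.5}
        )
        assert out[0][0].scale_factor == 0.5


class TestLoadCurves:
    def test_tabulated_all_factor_quarters_force(self):
        curve = np.array([[0.0, 0.0], [2.0, 100.0]])
        out = scale_load_curve(curve, 0.2500)  # mean ALL (C3-C5) factor
        np.testing.assert_allclose(out[:, 1], [0.0, 25.0])
        np.testing.assert_array_equal(out[:, 0], curve[:, 0])

    def test_identity_factor(self):
        curve = synthetic_load_curve("ALL")
        np.testing.assert_array_equal(scale_load_curve(curve, 1.0), curve)

    def test_four_springs_superpose_to_original(self):
        curve = synthetic_load_curve("ISL")
        quarter = scale_load_curve(curve, 0.25)
        np.testing.assert_allclose(4.0 * quarter[:, 1], curve[:, 1], rtol=1e-12)

    def test_scaling_is_multiplicative(self):
        curve = synthetic_load_curve("LF")
        ab = scale_load_curve(scale_load_curve(curve, 0.5), 0.4)
        np.testing.assert_allclose(ab, scale_load_curve(curve, 0.2), rtol=1e-12)

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            scale_load_curve(np.array([[0.0, 0.0], [1.0, 1.0]]), 0.0)

    def test_load_curve_invariants_enforced(self):
        with pytest.raises(ValueError, match="increase"):
            LigamentSpec(
                kind="ALL",
                level_group="C3-C5",
                spring_pairs=[(0, 1)],
                load_curve=[[0.0, 0.0], [0.0, 1.0]],
                scale_factor=1.0,
            )


class TestMaterials:
    def test_default_spec_matches_tabulated_values(self):
        spec = default_material_spec("C3-C5")
        assert spec.annulus_bulk_modulus == 10.99
        assert spec.nucleus_bulk_modulus == 2.19
        assert spec.nucleus_poisson == 0.49
        assert spec.nucleus_viscosity_coefficient == 0.3
        s_sum = sum(s for s, _ in spec.annulus_prony)
        assert abs(s_sum - 1.0) < 1e-12

    def test_c5t1_prony_sum_not_forced_to_one(self):
        # printed C5-T1 coefficients sum to 1.1422; no sum-to-one invariant
        s_sum = sum(s for s, _ in ANNULUS_PRONY["C5-T1"])
        assert abs(s_sum - 1.1422) < 1e-12

    def test_poisson_bounds_enforced(self):
        with pytest.raises(ValueError, match="Poisson"):
            MaterialSpec(
                annulus_bulk_modulus=10.0,
                annulus_prony=ANNULUS_PRONY["C3-C5"],
                nucleus_bulk_modulus=2.0,
                nucleus_poisson=0.6,
                nucleus_viscosity_coefficient=0.3,
            )
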