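import math

import numpy as np
import pytest

from atherosim.geometry import (
    GAMMA_I,
    GAMMA_L,
    GAMMA_M,
    GAMMA_R,
    GeometryError,
    boundary_curvature,
    build_annulus_domain,
    build_channel_domain,
    curvature_circumcircle,
    remesh,
)


def shoelace_area(mesh):
    """Polygon area of the domain's outer boundary loop (channel only)."""
    gi = mesh.boundary_nodes[GAMMA_I]
    gm = mesh.boundary_nodes[GAMMA_M]
    loop = np.vstack([mesh.points[gm], mesh.points[gi][::-1]])
    x, y = loop[:, 0], loop[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestChannelDomain:
    def test_flat_strip_area(self):
        m = build_channel_domain(0.1, 0.01, bump_amplitude=0.0, h=1e-3)
        assert m.area() == pytest.approx(0.1 * 0.01, rel=1e-2)

    def test_gaussian_bump_adds_analytic_area(self):
        A, w = 0.005, 0.02
        m = build_channel_domain(0.1, 0.01, A, w, h=5e-4)
        bump_area = A * w * math.sqrt(2 * math.pi)  # tails truncated at +-2.5w
        expected = 0.1 * 0.01 + bump_area
        assert m.area() == pytest.approx(expected, rel=2e-2)

    def test_boundary_node_count_scales_with_resolution(self):
        m1 = build_channel_domain(h=2e-3)
        m2 = build_channel_domain(h=1e-3)
        n1 = len(m1.boundary_nodes[GAMMA_I])
        n2 = len(m2.boundary_nodes[GAMMA_I])
        assert n2 == pytest.approx(2 * n1, abs=2)

    def test_all_four_tags_present_and_periodic_pairing_consistent(self):
        m = build_channel_domain(h=1e-3)
        assert set(m.boundary_nodes) == {GAMMA_I, GAMMA_M, GAMMA_L, GAMMA_R}
        left, right, tr = m.periodic_pairs
        assert np.allclose(m.points[right] - m.points[left], tr)

    def test_bump_pinching_lumen_rejected(self):
        with pytest.raises(GeometryError, match="pinches"):
            build_channel_domain(bump_amplitude=0.06, lumen_clearance=0.05)

    def test_triangles_positively_oriented_and_quality_bounded(self):
        m = build_channel_domain(h=1e-3)
        assert np.all(m.triangle_areas() > 0)
        assert m.min_quality() > 0.3

    def test_mesh_area_matches_boundary_shoelace(self):
        m = build_channel_domain(h=1e-3)
        assert m.area() == pytest.approx(shoelace_area(m), rel=1e-10)


class TestAnnulusDomain:
    def test_area_matches_analytic_annulus(self, annulus):
        assert annulus.area() == pytest.approx(math.pi * (1.0 - 0.81), rel=1e-2)

    def test_inner_boundary_resolution(self, annulus):
        n = len(annulus.boundary_nodes[GAMMA_I])
        assert n * 0.02 == pytest.approx(2 * math.pi * 0.9, rel=0.05)

    def test_area_error_decreases_under_refinement(self):
        exact = math.pi * (1.0 - 0.81)
        errs = [
            abs(build_annulus_domain(0.9, 1.0, h).area() - exact)
            for h in (0.08, 0.04, 0.02)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_radii_out_of_order_rejected(self):
        with pytest.raises(GeometryError):
            build_annulus_domain(1.0, 0.9)


class TestCurvature:
    def test_circle_curvature_magnitude_is_inverse_radius(self, annulus):
        # inner circle of the annulus: |kappa| = 1/R; the domain lies
        # outside the circle, so the sign is negative (concave toward the
        # lumen) under the convex-toward-lumen-positive convention
        k = boundary_curvature(annulus, GAMMA_I)
        assert np.allclose(k, -1.0 / 0.9, rtol=2e-3)
        k_outer = boundary_curvature(annulus, GAMMA_M)
        assert np.allclose(k_outer, 1.0 / 1.0, rtol=2e-3)

    def test_circle_error_is_second_order(self):
        errs = []
        for h in (0.08, 0.04, 0.02):
            m = build_annulus_domain(0.9, 1.0, h)
            k = boundary_curvature(m, GAMMA_I)
            errs.append(np.abs(k + 1.0 / 0.9).max())
        order = np.log2(errs[0] / errs[2]) / 2.0
        assert order > 1.5

    def test_straight_segment_has_zero_curvature(self):
        m = build_channel_domain(bump_amplitude=0.0, h=1e-3)
        k = boundary_curvature(m, GAMMA_I)
        assert np.abs(k).max() < 1e-8

    def test_bump_crest_curvature_positive_toward_lumen(self):
        A, w = 0.005, 0.02
        m = build_channel_domain(0.1, 0.01, A, w, h=5e-4)
        gi = m.boundary_nodes[GAMMA_I]
        crest = np.argmin(np.abs(m.points[gi, 0] - 0.05))
        k = boundary_curvature(m, GAMMA_I)
        assert k[crest] == pytest.approx(A / w**2, rel=0.05)

    def test_quadratic_fit_agrees_with_circumcircle_oracle(self, annulus):
        k_fit = boundary_curvature(annulus, GAMMA_I)
        k_circ = curvature_circumcircle(annulus, GAMMA_I)
        assert np.allclose(k_fit, k_circ, rtol=5e-3)

    def test_turning_number_of_convex_outer_boundary(self, annulus):
        # integral of kappa ds over the closed convex media boundary = 2 pi
        k = boundary_curvature(annulus, GAMMA_M)
        edges = annulus.boundary_edges(GAMMA_M)
        ds = np.linalg.norm(
            annulus.points[edges[:, 1]] - annulus.points[edges[:, 0]], axis=1
        )
        total = float((k * ds).sum())
        assert total == pytest.approx(2 * math.pi, rel=1e-3)


class TestRemesh:
    def test_zero_displacement_preserves_boundary_and_area(self):
        m = build_channel_domain(h=1e-3)
        gi = m.boundary_nodes[GAMMA_I]
        m2 = remesh(m, m.points[gi].copy())
        gi2 = m2.boundary_nodes[GAMMA_I]
        assert np.allclose(m2.points[gi2], m.points[gi], atol=1e-14)
        assert m2.area() == pytest.approx(m.area(), rel=1e-12)

    def test_uniform_inward_displacement_grows_annulus_by_shell(self, annulus):
        d = 0.005  # toward the axis = into the lumen = domain grows
        gi = annulus.boundary_nodes[GAMMA_I]
        normals = annulus.outward_normals(GAMMA_I)
        displaced = annulus.points[gi] + d * normals
        m2 = remesh(annulus, displaced)
        gained = m2.area() - annulus.area()
        assert gained == pytest.approx(2 * math.pi * 0.9 * d, rel=0.02)

    def test_quality_floor_restored_after_displacement(self):
        m = build_channel_domain(h=1e-3)
        gi = m.boundary_nodes[GAMMA_I]
        pts = m.points[gi].copy()
        pts[:, 1] += 2e-4 * np.sin(2 * np.pi * m.points[gi, 0] / 0.1)
        m2 = remesh(m, pts)
        assert m2.min_quality() >= 0.3

    def test_collapsing_displacement_raises(self):
        m = build_channel_domain(h=1e-3)
        gi = m.boundary_nodes[GAMMA_I]
        pts = m.points[gi].copy()
        pts[:, 1] = -0.001  # push through the media wall
        with pytest.raises(GeometryError):
            remesh(m, pts)
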