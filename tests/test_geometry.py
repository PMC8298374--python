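"""Shape templates, polygon measures, orientation recovery and morphing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphocell import (CellState, ShapeTemplate, cell_area, cell_csi,
                        generate_equilibrium_shape, morph_parameters,
                        optimal_rotation, polygon_area, polygon_perimeter,
                        rotation_matrix, shape_index)

A_E, B_E = 6.25, 4.0
A_H, B_H = 20.0 / math.sqrt(6.0), 5.0 / math.sqrt(6.0)


class TestTemplates:
    @pytest.mark.parametrize("template, closed_form", [
        (ShapeTemplate(kind="circle", R=5.0), 25.0 * math.pi),
        (ShapeTemplate(kind="ellipse", a_e=A_E, b_e=B_E),
         math.pi * A_E * B_E),
        # astroid (a/b = 4): area (3/8)π a² — equal to the ellipse's 25π,
        # the equal-volume phenotype condition
        (ShapeTemplate(kind="hypocycloid", a_h=A_H, b_h=B_H),
         0.375 * math.pi * A_H ** 2),
    ])
    def test_polygon_area_converges_to_closed_form(self, template,
                                                   closed_form):
        off = generate_equilibrium_shape(template, 4096)
        assert polygon_area(off) == pytest.approx(closed_form, rel=1e-3)

    def test_equal_volume_phenotypes(self):
        assert math.pi * A_E * B_E == pytest.approx(
            0.375 * math.pi * A_H ** 2, rel=1e-12)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShapeTemplate(kind="circle", R=-1.0)
        with pytest.raises(ValueError):
            ShapeTemplate(kind="ellipse", a_e=1.0, b_e=2.0)
        with pytest.raises(ValueError):
            generate_equilibrium_shape(ShapeTemplate(kind="circle"), 3)

    def test_offsets_are_centred(self):
        off = generate_equilibrium_shape(ShapeTemplate(kind="ellipse"), 40)
        np.testing.assert_allclose(off.mean(axis=0), 0.0, atol=1e-12)


class TestMorphing:
    def setup_method(self):
        self.tmpl = ShapeTemplate(kind="morphing", a_e=A_E, b_e=B_E,
                                  a_h=A_H, b_h=B_H, lam_w=10.0, t_w=2.0)

    def test_onset_returns_elliptic_parameters(self):
        assert morph_parameters(2.0, self.tmpl) == pytest.approx((A_E, B_E))
        assert morph_parameters(0.5, self.tmpl) == pytest.approx((A_E, B_E))

    def test_long_time_limit_is_hypocycloid(self):
        ra, rb = morph_parameters(2.0 + 5.0, self.tmpl)
        assert (ra, rb) == pytest.approx((A_H, B_H), rel=1e-6)

    def test_half_life_midpoint(self):
        t_half = 2.0 + math.log(2.0) / 10.0
        ra, _ = morph_parameters(t_half, self.tmpl)
        assert ra == pytest.approx(0.5 * (A_H + A_E), rel=1e-12)

    @pytest.mark.parametrize("omega", [0.0, 0.25, 0.5, 0.75, 0.999])
    def test_morph_preserves_area_within_two_percent(self, omega):
        t = (2.0 if omega == 0.0
             else 2.0 - math.log(1.0 - omega) / 10.0)
        off = generate_equilibrium_shape(self.tmpl, 1024, t=t)
        assert polygon_area(off) == pytest.approx(25.0 * math.pi, rel=0.02)


class TestPolygonMeasures:
    def test_unit_square(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        assert polygon_area(sq) == pytest.approx(1.0)
        assert shape_index(sq) == pytest.approx(math.pi / 4.0)

    def test_inscribed_polygon_area_formula(self):
        # circle R=5, N=40: shoelace equals (1/2) N R² sin(2π/N)
        off = generate_equilibrium_shape(ShapeTemplate(kind="circle", R=5.0),
                                         40)
        expected = 0.5 * 40 * 25.0 * math.sin(2.0 * math.pi / 40.0)
        assert polygon_area(off) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_polygon_flagged(self):
        collinear = np.array([[0, 0], [1, 0], [2, 0], [3, 0.0]])
        cell = CellState(nodes=collinear, offsets=collinear,
                         csi0=1.0, area0=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            assert cell_area(cell) == 0.0

    def test_zero_perimeter_is_an_error(self):
        with pytest.raises(ValueError, match="perimeter"):
            shape_index(np.zeros((4, 2)))

    def test_ellipse_csi_against_quadrature_perimeter(self):
        # independent oracle: ellipse circumference by adaptive quadrature
        from scipy.integrate import quad
        a, b = A_E, B_E
        peri, _ = quad(lambda t: math.hypot(a * math.sin(t),
                                            b * math.cos(t)),
                       0.0, 2.0 * math.pi, limit=200)
        expected = 4.0 * math.pi * (math.pi * a * b) / peri ** 2
        off = generate_equilibrium_shape(
            ShapeTemplate(kind="ellipse", a_e=a, b_e=b), 4096)
        assert shape_index(off) == pytest.approx(expected, abs=1e-4)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=5, max_value=60),
           st.integers(min_value=0, max_value=10 ** 6))
    def test_csi_bounded_by_isoperimetric_inequality(self, n, seed):
        # random star-shaped polygons are simple; their CSI never exceeds 1
        rng = np.random.default_rng(seed)
        theta = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=n))
        if np.min(np.diff(theta), initial=1.0) < 1e-6:
            theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        r = rng.uniform(0.5, 3.0, size=n)
        poly = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        assert shape_index(poly) <= 1.0 + 1e-12

    def test_rotation_translation_scale_invariance(self, rng):
        off = generate_equilibrium_shape(ShapeTemplate(kind="ellipse"), 64)
        moved = 3.0 * off @ rotation_matrix(0.7).T + np.array([11.0, -4.0])
        assert shape_index(moved) == pytest.approx(shape_index(off),
                                                   rel=1e-12)


class TestOptimalRotation:
    def setup_method(self):
        self.eq = generate_equilibrium_shape(ShapeTemplate(kind="ellipse"),
                                             40)

    def test_identity(self):
        phi, B, degenerate = optimal_rotation(self.eq, self.eq)
        assert phi == pytest.approx(0.0, abs=1e-12)
        assert not degenerate

    def test_exact_recovery_of_rotation(self):
        cur = self.eq @ rotation_matrix(math.pi / 6.0).T
        phi, _, _ = optimal_rotation(self.eq, cur)
        assert phi == pytest.approx(math.pi / 6.0, abs=1e-12)

    def test_closed_form_matches_grid_search(self, rng):
        # brute-force oracle: scan 10^6 angles of the least-squares objective
        cur = self.eq @ rotation_matrix(1.234).T
        cur = cur + 0.05 * np.linalg.norm(self.eq, axis=1)[:, None] \
            * rng.standard_normal(cur.shape)
        phi, _, _ = optimal_rotation(self.eq, cur)
        grid = np.linspace(0.0, 2.0 * np.pi, 10 ** 6, endpoint=False)
        dot = float(np.sum(self.eq * cur))
        cross = float(np.sum(self.eq[:, 0] * cur[:, 1]
                             - self.eq[:, 1] * cur[:, 0]))
        objective = -(np.cos(grid) * dot + np.sin(grid) * cross)
        phi_grid = grid[np.argmin(objective)]
        assert phi == pytest.approx(phi_grid, abs=2.0 * np.pi / 10 ** 6)

    def test_never_worse_than_no_rotation(self, rng):
        for _ in range(20):
            cur = self.eq @ rotation_matrix(rng.uniform(0, 2 * np.pi)).T \
                + 0.3 * rng.standard_normal(self.eq.shape)
            cur = cur - cur.mean(axis=0)
            phi, B, _ = optimal_rotation(self.eq, cur)
            obj_rot = np.sum((self.eq @ B.T - cur) ** 2)
            obj_id = np.sum((self.eq - cur) ** 2)
            assert obj_rot <= obj_id + 1e-9

    def test_degenerate_offsets_flagged(self):
        phi, B, degenerate = optimal_rotation(np.zeros((5, 2)),
                                              np.zeros((5, 2)))
        assert degenerate and phi == 0.0
        np.testing.assert_allclose(B, np.eye(2))


class TestCellState:
    def test_centre_is_node_mean(self, circle_cell):
        np.testing.assert_allclose(circle_cell.centre,
                                   circle_cell.nodes.mean(axis=0))

    def test_equilibrium_references_set(self, circle_cell):
        assert circle_cell.area0 == pytest.approx(
            polygon_area(circle_cell.offsets))
        assert circle_cell.csi0 == pytest.approx(
            shape_index(circle_cell.offsets))
        assert cell_csi(circle_cell) == pytest.approx(circle_cell.csi0)

    def test_segment_normals_point_inward(self, circle_cell):
        mid, ln, n_in = circle_cell.segments()
        # moving from the midpoint along the inward normal approaches centre
        closer = np.linalg.norm(mid + 0.1 * n_in - circle_cell.centre, axis=1)
        farther = np.linalg.norm(mid - circle_cell.centre, axis=1)
        assert np.all(closer < farther)
        assert ln.sum() == pytest.approx(circle_cell.perimeter())

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError, match="4"):
            CellState(nodes=np.zeros((3, 2)), offsets=np.zeros((3, 2)),
                      csi0=1.0, area0=1.0)
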