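"""Traction, Hertz contact and microchannel wall forces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphocell import (CellState, ShapeTemplate, TubeGeometry,
                        cell_cell_forces, detect_cell_cell_contacts,
                        equivalent_modulus, hertz_total_force,
                        microtube_wall_forces, traction_forces)


def circle(centre, R=5.0, N=40):
    return CellState.from_template(ShapeTemplate(kind="circle", R=R),
                                   centre=centre, N=N)


class TestTraction:
    def test_closed_polygon_zero_resultant_and_torque(self, circle_cell):
        fs = traction_forces(circle_cell)
        total = np.abs(fs.resultant).max()
        scale = np.linalg.norm(fs.forces, axis=1).sum()
        assert total / scale < 1e-10
        assert abs(fs.torque_about(circle_cell.centre)) / scale < 1e-10

    def test_square_cell_four_inward_forces(self):
        sq = np.array([[0, 0], [2, 0], [2, 2], [0, 2.0]])
        cell = CellState(nodes=sq, offsets=sq - sq.mean(axis=0), P=3.0)
        fs = traction_forces(cell)
        mags = np.linalg.norm(fs.forces, axis=1)
        np.testing.assert_allclose(mags, 3.0 * 2.0)   # P × side length
        # every force points from the segment midpoint toward the centre
        toward = sq.mean(axis=0) - fs.points
        dots = np.einsum("ij,ij->i", fs.forces, toward)
        assert np.all(dots > 0.0)

    def test_total_magnitude_is_p_times_perimeter(self, circle_cell):
        fs = traction_forces(circle_cell)
        assert np.linalg.norm(fs.forces, axis=1).sum() == pytest.approx(
            circle_cell.P * circle_cell.perimeter(), rel=1e-12)

    def test_zero_length_segment_skipped_with_warning(self):
        nodes = np.array([[0, 0], [1, 0], [1, 0], [1, 1], [0, 1.0]])
        cell = CellState(nodes=nodes, offsets=nodes - nodes.mean(axis=0))
        with pytest.warns(UserWarning, match="zero-length"):
            fs = traction_forces(cell)
        assert len(fs.points) == 4

    def test_negative_traction_rejected(self, circle_cell):
        with pytest.raises(ValueError, match="non-negative"):
            traction_forces(circle_cell, P=-1.0)


class TestHertz:
    def test_equal_bodies_closed_form(self):
        assert equivalent_modulus(5.0, 0.32, 5.0, 0.32) == pytest.approx(
            5.0 / (2.0 * (1.0 - 0.32 ** 2)))
        assert equivalent_modulus(5.0, 0.32, 5.0, 0.32) == pytest.approx(
            2.785, abs=5e-4)

    def test_rigid_wall_limit(self):
        assert equivalent_modulus(5.0, 0.32) == pytest.approx(
            5.0 / (1.0 - 0.32 ** 2))

    def test_symmetry_in_body_exchange(self):
        assert equivalent_modulus(3.0, 0.2, 7.0, 0.4) == pytest.approx(
            equivalent_modulus(7.0, 0.4, 3.0, 0.2))

    def test_invalid_moduli_rejected(self):
        with pytest.raises(ValueError):
            equivalent_modulus(-1.0, 0.3)
        with pytest.raises(ValueError):
            equivalent_modulus(1.0, 1.2)

    def test_unit_evaluation(self):
        assert hertz_total_force(0.0, 1.0) == 0.0
        assert hertz_total_force(1.0, 1.0) == pytest.approx(math.pi / 4.0)
        assert hertz_total_force(-0.5, 1.0) == 0.0   # no tensile contact

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=0.0, max_value=10.0),
           st.floats(min_value=0.1, max_value=500.0),
           st.floats(min_value=-0.45, max_value=0.45))
    def test_formula_against_scalar_oracle(self, d, E, nu):
        # independent oracle: (π/4) d / [(1−ν²)/E · 2]
        e_star = 1.0 / (2.0 * (1.0 - nu ** 2) / E)
        expected = 0.25 * math.pi * d * e_star
        got = hertz_total_force(d, equivalent_modulus(E, nu, E, nu))
        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_monotone_in_depth(self):
        forces = [hertz_total_force(d, 2.785) for d in np.linspace(0, 5, 20)]
        assert np.all(np.diff(forces) >= 0.0)


class TestCellCellContact:
    def test_disjoint_cells_no_contact(self):
        c = detect_cell_cell_contacts(circle((0, 0)), circle((12, 0)))
        assert c.is_empty

    def test_tangent_cells_no_contact(self):
        c = detect_cell_cell_contacts(circle((0, 0)), circle((10.0, 0)))
        assert c.is_empty

    def test_overlapping_envelopes(self):
        # two R=5 discs, centres 9 apart: envelope overlap depth 1 μm;
        # geometric oracle — contact segments symmetric about the axis
        ci, ck = circle((0, 0)), circle((9.0, 0))
        c = detect_cell_cell_contacts(ci, ck)
        assert not c.is_empty
        np.testing.assert_allclose(c.depths, 1.0, rtol=1e-12)
        mids = ci.segments()[0][c.segment_indices]
        assert abs(mids[:, 1].mean()) < 1e-9
        assert c.contact_length == pytest.approx(
            ci.segments()[1][c.segment_indices].sum())

    def test_equivalent_modulus_identity_holds(self):
        c = detect_cell_cell_contacts(circle((0, 0)), circle((9.0, 0)))
        inv = 2.0 * (1.0 - 0.32 ** 2) / 5.0
        assert 1.0 / c.E_star == pytest.approx(inv, rel=1e-12)

    def test_full_overlap_flagged(self):
        with pytest.warns(UserWarning, match="full overlap"):
            c = detect_cell_cell_contacts(circle((0, 0)), circle((0, 0)))
        assert c.full_overlap

    def test_empty_contact_reduces_to_traction(self, circle_cell):
        c = detect_cell_cell_contacts(circle_cell, circle((100.0, 0)))
        fs = cell_cell_forces(circle_cell, c)
        ref = traction_forces(circle_cell)
        np.testing.assert_allclose(fs.forces, ref.forces)

    def test_symmetric_collision_equal_opposite_resultants(self):
        ci, ck = circle((0, 0)), circle((9.0, 0))
        fi = cell_cell_forces(ci, detect_cell_cell_contacts(ci, ck), P=0.0)
        fk = cell_cell_forces(ck, detect_cell_cell_contacts(ck, ci), P=0.0)
        np.testing.assert_allclose(fi.resultant, -fk.resultant, atol=1e-10)

    def test_contact_forces_sum_to_hertz_total(self):
        ci, ck = circle((0, 0)), circle((9.0, 0))
        c = detect_cell_cell_contacts(ci, ck)
        fs = cell_cell_forces(ci, c, P=0.0)
        mags = np.linalg.norm(fs.forces[c.segment_indices], axis=1)
        assert mags.sum() == pytest.approx(
            hertz_total_force(1.0, c.E_star), rel=1e-10)


class TestWallForces:
    def setup_method(self):
        self.tube = TubeGeometry(entrance_x=0.0, axis_y=0.0)

    def test_uncompressed_free_cell_no_force(self):
        cell = circle((-30.0, 0.0), R=9.0)
        fs = microtube_wall_forces(cell, self.tube)
        assert len(fs.points) == 0

    def test_cell_in_lc_always_contacts_walls(self):
        # R=9 exceeds the 7.5 μm half-width: a cell inside the LC is always
        # compressed and pushes on both walls
        cell = circle((25.0, 0.0), R=9.0)
        cell.nodes = self.tube.clamp(cell.nodes)
        fs = microtube_wall_forces(cell, self.tube)
        assert len(fs.points) > 0
        assert np.any(fs.forces[:, 1] > 0) and np.any(fs.forces[:, 1] < 0)

    def test_compressed_node_force_magnitude(self):
        # node compressed to distance R−2 → per-length (π/4)·2·E*/‖l_m‖
        cell = circle((25.0, 0.0), R=9.0)
        cell.nodes = self.tube.clamp(cell.nodes)
        fs = microtube_wall_forces(cell, self.tube)
        e_star = equivalent_modulus(cell.E_c_elastic, cell.nu_c)
        d = cell.R - np.linalg.norm(fs.points - cell.centre, axis=1)
        for patch in fs.patches:
            sel = patch["indices"]
            expected = 0.25 * math.pi * np.clip(d[sel], 0, None) \
                * e_star / patch["lm"] * fs.lengths[sel]
            np.testing.assert_allclose(
                np.linalg.norm(fs.forces[sel], axis=1), expected, rtol=1e-9)

    def test_forces_push_outward_onto_walls(self):
        cell = circle((25.0, 0.0), R=9.0)
        cell.nodes = self.tube.clamp(cell.nodes)
        fs = microtube_wall_forces(cell, self.tube)
        # the y-component always points away from the channel axis
        assert np.all(fs.forces[:, 1] * fs.points[:, 1] >= 0.0)
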