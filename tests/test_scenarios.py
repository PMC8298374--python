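"""Scenario drivers, phase detection and Monte Carlo machinery."""

import math
from dataclasses import replace

import numpy as np
import pytest

from morphocell import (PointForceSet, TABLE6_MC_ERRORS, TubeGeometry,
                        contact_pressure, default_config, detect_phases,
                        mc_error, phase3_probability_from_error,
                        run_collision_scenario, run_differentiation_scenario,
                        run_microtube_scenario, run_monte_carlo)
from morphocell.scenarios import wall_pressure


def mc_scale_config():
    """Coarse desk-scale microtube configuration for repeated transits."""
    return replace(default_config("microtube"), t_end=90.0, mesh_h=40.0,
                   mesh_h_fine=4.5, runup=6.0)


@pytest.fixture(scope="module")
def tube():
    return TubeGeometry(entrance_x=0.0, axis_y=0.0)


def synthetic_transit(tube, backward_at=None, n=600, speed=1.0, dt=0.25):
    """Hand-built monotone transit; optionally one backward centre step."""
    t = dt * np.arange(1, n + 1)
    centre = -20.0 + speed * dt * np.arange(n)
    if backward_at is not None:
        centre[backward_at:] -= 2.0 * speed * dt   # one backward step
    front = centre + 9.0
    rear = centre - 9.0
    return t, front, rear, centre


class TestPhaseDetection:
    def test_monotone_transit_has_no_phase3(self, tube):
        t, f, r, c = synthetic_transit(tube)
        tl = detect_phases(t, f, r, c, tube)
        assert not tl.phase3_occurred
        assert set(tl.intervals) == {1, 2, 4}
        assert tl.complete

    def test_injected_backward_step_yields_phase3(self, tube):
        t, f, r, c = synthetic_transit(tube)
        # place the backward step while the cell overlaps the SNB
        idx = int(np.argmax((f >= tube.x1) & (r <= tube.x2))) + 10
        t, f, r, c = synthetic_transit(tube, backward_at=idx)
        tl = detect_phases(t, f, r, c, tube)
        assert tl.phase3_occurred
        assert 3 in tl.intervals
        assert tl.intervals[3][0] == pytest.approx(t[idx])

    def test_phases_partition_the_transit(self, tube):
        for backward in (None, 260):
            t, f, r, c = synthetic_transit(tube, backward_at=backward)
            tl = detect_phases(t, f, r, c, tube)
            keys = sorted(tl.intervals)
            for a, b in zip(keys[:-1], keys[1:]):
                assert tl.intervals[a][1] == pytest.approx(
                    tl.intervals[b][0])

    def test_backward_step_outside_snb_is_not_phase3(self, tube):
        t, f, r, c = synthetic_transit(tube, backward_at=20)  # before entry
        tl = detect_phases(t, f, r, c, tube)
        assert not tl.phase3_occurred

    def test_never_entered_returns_none(self, tube):
        t = np.arange(1, 10) * 0.1
        x = np.full(9, -50.0)
        assert detect_phases(t, x + 9, x - 9, x, tube) is None


class TestPressure:
    def test_no_contact_zero_pressure(self):
        assert contact_pressure(PointForceSet.empty("wall"), 0.0) == 0.0

    def test_single_segment_definition(self):
        fs = PointForceSet(np.zeros((1, 2)), np.array([[0.0, 3.0]]),
                           np.array([2.0]), "wall")
        # F/(L·1μm) in kg/(μm·min²), converted: 1 unit = 277.78 Pa
        assert contact_pressure(fs, 2.0) == pytest.approx(
            3.0 / 2.0 * 0.27778, rel=1e-3)

    def test_linearity_in_force(self):
        fs1 = PointForceSet(np.zeros((2, 2)),
                            np.array([[1.0, 0.0], [0.0, 2.0]]),
                            np.ones(2), "wall")
        fs2 = PointForceSet(fs1.points, 2.0 * fs1.forces, fs1.lengths, "wall")
        assert contact_pressure(fs2, 2.0) == pytest.approx(
            2.0 * contact_pressure(fs1, 2.0))

    def test_wall_pressure_defaults_to_global_without_patches(self):
        fs = PointForceSet(np.zeros((1, 2)), np.array([[0.0, 3.0]]),
                           np.array([2.0]), "wall")
        assert wall_pressure(fs) == pytest.approx(contact_pressure(fs, 2.0))


class TestMonteCarloMachinery:
    def test_error_formula(self):
        assert mc_error(0.5, 100) == pytest.approx(0.05)
        assert mc_error(0.0, 7) == 0.0
        assert mc_error(1.0, 7) == 0.0

    def test_published_errors_invert_to_valid_probabilities(self):
        # algebraic inversion of sqrt(p(1-p)/n) for each published row
        for mech, (n, err) in TABLE6_MC_ERRORS.items():
            lo, hi = phase3_probability_from_error(n, err)
            assert 0.0 < lo < hi < 1.0
            assert mc_error(lo, n) == pytest.approx(err, rel=1e-6)
            assert mc_error(hi, n) == pytest.approx(err, rel=1e-6)

    def test_impossible_error_rejected(self):
        with pytest.raises(ValueError, match="valid probability"):
            phase3_probability_from_error(100, 0.2)

    def test_single_deterministic_sample(self):
        cfg = replace(mc_scale_config(), sigma_rw=0.0)
        res = run_monte_carlo(cfg, "fixed-10", n=1, seed=4)
        assert res.phase3_probability in (0.0, 1.0)
        assert res.mc_error == 0.0

    def test_seeded_mc_reproducible(self):
        cfg = mc_scale_config()
        a = run_monte_carlo(cfg, "fixed-10", n=2, seed=9)
        b = run_monte_carlo(cfg, "fixed-10", n=2, seed=9)
        assert a.phase3_probability == b.phase3_probability
        assert a.samples == b.samples


@pytest.fixture(scope="module")
def transit():
    return run_microtube_scenario(mc_scale_config(), "fixed-10", seed=5)


class TestMicrotubeTransit:
    def test_transit_completes(self, transit):
        assert transit.completed
        assert transit.timeline.complete

    def test_free_runup_uncompressed_at_full_speed(self, transit):
        # before wall contact the cell runs at the prescribed speed
        assert transit.pressure[0] == 0.0
        assert transit.speed_smoothed[2] == pytest.approx(10.0, abs=3.0)
        assert transit.csi[0] > 0.95

    def test_wall_non_penetration_throughout(self, transit):
        tube = transit.tube
        # front/rear stay consistent and the shape index stays positive
        assert np.all(transit.front_x >= transit.rear_x)
        assert np.all(transit.csi > 0.0)

    def test_snb_slowdown_and_recovery(self, transit):
        tube = transit.tube
        ov = (transit.front_x >= tube.x1) & (transit.rear_x <= tube.x2)
        after = transit.rear_x > tube.x2
        assert transit.speed_smoothed[ov].min() \
            < 0.5 * transit.speed_smoothed[after].max()
        assert transit.csi[ov].min() < transit.csi[after].max() - 0.2

    def test_phase_timeline_ordered(self, transit):
        tl = transit.timeline
        keys = sorted(tl.intervals)
        assert keys[0] == 1 and keys[-1] == 4
        for k in keys:
            t0, t1 = tl.intervals[k]
            assert t1 >= t0 - 1e-9


@pytest.fixture(scope="module")
def result():
    cfg = replace(default_config("collision"), sigma_rw=0.0, t_end=16.0)
    return run_collision_scenario(cfg)


class TestCollisionScenario:
    def test_cells_never_interpenetrate_beyond_node_tolerance(self, result):
        # node-level non-penetration: discretisation-scale tolerance
        assert result.extras["min_gap"] > -0.1

    def test_mirror_symmetry_preserved(self, result):
        c = result.centres
        asym = np.abs(c[:, 0, 0] + c[:, 1, 0] - 120.0).max()
        assert asym < 0.1

    def test_facing_membranes_flatten(self, result):
        assert result.csi.min() < 0.9

    def test_csi_recovers_after_engulfment(self, result):
        assert np.all(result.csi[-1] > 0.98)


class TestDifferentiationScenario:
    def test_cell_below_threshold_stays_elliptic(self):
        cfg = replace(default_config("differentiation"), sigma_rw=0.0,
                      t_end=3.0, c_diff=1e9)
        res = run_differentiation_scenario(cfg)
        assert all(t is None for t in res.extras["t_onset"])
        assert np.all(res.extras["omega"] == 0.0)
        assert all(c.phenotype == "fibroblast" for c in res.cells)

    def test_morphing_follows_exponential_progress(self):
        cfg = replace(default_config("differentiation"), sigma_rw=0.0,
                      t_end=4.0)
        res = run_differentiation_scenario(cfg)
        onset = res.extras["t_onset"][0]
        assert onset is not None
        steps = np.arange(1, len(res.times) + 1) * cfg.dt
        expected = np.where(steps >= onset,
                            1.0 - np.exp(-cfg.lambda_w * (steps - onset)),
                            0.0)
        np.testing.assert_allclose(res.extras["omega"][:, 0], expected,
                                   atol=1e-9)

    def test_differentiated_cells_deform_substrate_more(self):
        runs = {}
        for fac in (1.0, 2.0):
            cfg = replace(default_config("differentiation"), sigma_rw=0.0,
                          t_end=5.0, traction_factor=fac)
            res = run_differentiation_scenario(cfg)
            runs[fac] = res.extras["u_near"][-1].mean()
        assert runs[2.0] > 1.5 * runs[1.0]
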