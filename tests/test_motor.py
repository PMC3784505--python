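import numpy as np
import pytest

from vibrisim import motor
from vibrisim.attention import deposit_blobs
from vibrisim.motor import (FoveationPlan, WhiskerCommand, arbitrated_angle,
                            build_geom_table, foveation_target, map_contrast,
                            max_protraction, min_jerk, oscillator_step,
                            proposed_angles, whisk_step)
from vibrisim.params import Params
from vibrisim.plane import HeadPose, arc_polyline


@pytest.fixture(scope="module")
def geom(params=Params()):
    from vibrisim.attention import GridSpec
    from vibrisim.plane import build_morphology
    spec = GridSpec(params)
    morphs = build_morphology(params)
    table = build_geom_table(morphs, spec, params)
    theta_prop, mask = proposed_angles(table, params)
    return params, spec, morphs, table, theta_prop, mask


class TestOscillator:
    def test_drive_duty_cycle(self, params):
        ts = np.arange(0, params.oscillator_period, params.sample_dt / 4)
        qs = np.array([oscillator_step(t, params)[1] for t in ts])
        frac_high = qs.mean()
        assert frac_high == pytest.approx(params.duty_cycle, abs=0.02)
        # retraction first, protraction later in the cycle
        assert qs[0] == 0 and qs[-1] == 1

    def test_eight_ticks_per_second(self, params):
        ts = np.arange(0, 1.0 + 1e-12, params.sample_dt)
        ticks = sum(oscillator_step(t, params)[0] for t in ts)
        assert ticks == 8

    def test_negative_time_rejected(self, params):
        with pytest.raises(ValueError):
            oscillator_step(-0.1, params)


class TestMinJerk:
    def plan(self):
        return FoveationPlan(start=np.array([0.0, 0.0]),
                             target=np.array([40.0, 30.0]),
                             t0=1.0, duration=0.175)

    def test_endpoints_and_midpoint(self):
        p = self.plan()
        np.testing.assert_allclose(min_jerk(p, 1.0), p.start)
        np.testing.assert_allclose(min_jerk(p, 1.175), p.target)
        np.testing.assert_allclose(min_jerk(p, 1.0875),
                                   (p.start + p.target) / 2.0)

    def test_clamps_outside_span(self):
        p = self.plan()
        np.testing.assert_allclose(min_jerk(p, 0.0), p.start)
        np.testing.assert_allclose(min_jerk(p, 5.0), p.target)

    def test_peak_speed_is_15_over_8(self):
        """Dense evaluation recovers the closed-form minimum-jerk factor."""
        p = self.plan()
        ts = np.linspace(1.0, 1.175, 20001)
        pos = np.array([min_jerk(p, t) for t in ts])
        speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) / np.diff(ts)
        expected = 1.875 * np.linalg.norm(p.target - p.start) / p.duration
        assert speed.max() == pytest.approx(expected, rel=1e-4)


class TestFoveationTarget:
    def test_single_peak(self, grid, pose0):
        S = grid.zeros()
        S[12, 40] = 0.8
        t = foveation_target(grid, S, pose0)
        from vibrisim.plane import FrameTransform
        np.testing.assert_allclose(
            FrameTransform(pose0).head_from_world(t),
            grid.cell_center(12, 40), atol=1e-9)

    def test_empty_map_stays(self, grid, pose0):
        np.testing.assert_allclose(foveation_target(grid, grid.zeros(), pose0),
                                   pose0.fovea)

    def test_tie_broken_by_distance(self, grid, pose0):
        S = grid.zeros()
        near = (grid.nx // 2 + 2, grid.ny // 2)
        far = (grid.nx - 1, grid.ny - 1)
        S[near] = 0.7
        S[far] = 0.7
        t = foveation_target(grid, S, pose0)
        from vibrisim.plane import FrameTransform
        np.testing.assert_allclose(
            FrameTransform(pose0).head_from_world(t),
            grid.cell_center(*near), atol=1e-9)


class TestGeomTable:
    def test_straight_whisker_angle_equals_cell_bearing(self, geom):
        params, spec, morphs, *_ = geom
        from vibrisim.attention import GridSpec
        m0 = morphs[0]
        straight = type(m0)(side=m0.side, index=m0.index,
                            base_point=m0.base_point,
                            base_tangent=m0.base_tangent, length=m0.length,
                            rest_curvature=0.0)
        table = build_geom_table([straight], spec, params)
        rng = np.random.default_rng(1)
        for e in rng.integers(0, spec.nx * spec.ny, 50):
            if table.code[0, e] != motor.REACHABLE:
                continue
            d = spec.centers[e] - m0.base_point
            phi = np.degrees(np.arctan2(d[1], d[0]))
            expected = (180.0 - phi) % 360.0      # left-side convention
            got = table.theta_geom[0, e] % 360.0
            assert abs((got - expected + 180) % 360 - 180) < 0.5

    def test_arc_passes_through_reachable_cells(self, geom):
        params, spec, morphs, table, *_ = geom
        rng = np.random.default_rng(2)
        checked = 0
        for i in (0, 4, 9, 13):
            m = morphs[i]
            for e in rng.integers(0, spec.nx * spec.ny, 80):
                if table.code[i, e] != motor.REACHABLE:
                    continue
                poly = arc_polyline(m, table.theta_geom[i, e],
                                    m.rest_curvature, step=0.2)
                dmin = np.min(np.linalg.norm(poly - spec.centers[e], axis=1))
                assert dmin < 1.0
                checked += 1
        assert checked > 50

    def test_far_cells_marked(self, geom):
        params, spec, morphs, table, *_ = geom
        m = morphs[6]   # most rostral left whisker, 8 mm
        d = np.linalg.norm(spec.centers - m.base_point, axis=1)
        far = d > m.length + 1.0
        assert np.all(table.code[6, far] == motor.UNREACHABLE_FAR)


class TestArbitration:
    def test_proposals_clip_and_reach(self, geom):
        params, spec, morphs, table, theta_prop, mask = geom
        far = table.code == motor.UNREACHABLE_FAR
        assert np.all(theta_prop[far] == params.theta_max)
        assert np.all(theta_prop >= params.theta_min)
        assert np.all(theta_prop <= params.theta_max)
        # caudally out-of-range cells carry no vote
        caudal_out = (table.code == motor.REACHABLE) & \
            (table.theta_geom < params.theta_min)
        assert not np.any(mask & caudal_out)

    def test_single_active_cell_wins(self, geom):
        params, spec, morphs, table, theta_prop, mask = geom
        S = np.zeros(spec.nx * spec.ny)
        e = np.flatnonzero(mask[0] & (table.code[0] == motor.REACHABLE) &
                           (table.theta_geom[0] > params.theta_min) &
                           (table.theta_geom[0] < params.theta_max))[10]
        S[e] = 1.0
        th = arbitrated_angle(S, theta_prop, mask, params)
        assert th[0] == pytest.approx(theta_prop[0, e])

    def test_empty_map_falls_back_to_nominal(self, geom):
        params, spec, morphs, table, theta_prop, mask = geom
        th = arbitrated_angle(np.zeros(spec.nx * spec.ny), theta_prop, mask,
                              params)
        np.testing.assert_allclose(th, np.tile(params.theta_nom, 2))

    def test_caudal_bias_pulls_below_unweighted_mean(self, geom):
        """Two equally active cells: the more caudal proposal dominates."""
        params, spec, morphs, table, theta_prop, mask = geom
        i = 0
        ok = mask[i] & (table.code[i] == motor.REACHABLE)
        props = np.where(ok, theta_prop[i], np.nan)
        e_caudal = np.nanargmin(np.abs(props - 60.0))
        e_rostral = np.nanargmin(np.abs(props - 160.0))
        S = np.zeros(spec.nx * spec.ny)
        S[e_caudal] = 0.5
        S[e_rostral] = 0.5
        th = arbitrated_angle(S, theta_prop, mask, params)
        mean = (theta_prop[i, e_caudal] + theta_prop[i, e_rostral]) / 2
        assert th[i] < mean

    def test_matches_brute_force_summation(self, geom):
        """Vectorised weighted vote equals an explicit per-cell loop."""
        params, spec, morphs, table, theta_prop, mask = geom
        rng = np.random.default_rng(3)
        S = np.where(rng.random(spec.nx * spec.ny) < 0.01,
                     rng.random(spec.nx * spec.ny), 0.0)
        th = arbitrated_angle(S, theta_prop, mask, params)
        floor = motor.activity_floor(params)
        for i in (0, 7, 13):
            num = den = 0.0
            for e in range(spec.nx * spec.ny):
                if not mask[i, e] or S[e] < floor:
                    continue
                w = (params.activity_gain * S[e]) ** params.activity_exponent
                w *= params.caudal_bias_base ** (
                    -(theta_prop[i, e] - params.theta_min)
                    / (params.theta_max - params.theta_min))
                num += w * theta_prop[i, e]
                den += w
            expected = num / den if den > 0 else np.tile(params.theta_nom, 2)[i]
            assert th[i] == pytest.approx(expected, rel=1e-9)


class TestContrastAndModulation:
    def test_contrast_limits(self, grid):
        assert map_contrast(grid.zeros()) == 0.0
        assert map_contrast(np.full(grid.shape, 0.5)) == 0.0
        S = grid.zeros()
        S[3, 3] = 1.0
        assert map_contrast(S) == pytest.approx(1.0, abs=0.01)

    def test_modulation_arithmetic(self, params):
        th_nom = np.tile(params.theta_nom, 2)
        th_hat = th_nom + 40.0
        out = max_protraction(th_hat, 1.0, params)
        np.testing.assert_allclose(out, th_nom + params.modulation_strength
                                    * 40.0)
        np.testing.assert_allclose(max_protraction(th_hat, 0.0, params),
                                   th_nom)
        p0 = params.replace(modulation_strength=0.0)
        np.testing.assert_allclose(max_protraction(th_hat, 1.0, p0), th_nom)

    def test_modulated_angle_stays_in_range(self, params):
        rng = np.random.default_rng(0)
        th_hat = rng.uniform(params.theta_min, params.theta_max, 14)
        for C in (0.0, 0.3, 1.0):
            out = max_protraction(th_hat, C, params)
            assert np.all(out >= params.theta_min - 1e-9)
            assert np.all(out <= params.theta_max + 1e-9)


class TestWhisking:
    def test_amplitudes_follow_reference_range(self, params):
        np.testing.assert_allclose(params.amplitudes[[0, -1]], [30.0, 45.0])

    def test_fixed_point_at_target(self, params):
        cmd = WhiskerCommand(np.full(14, 120.0), np.full(14, 120.0),
                             np.tile(params.amplitudes, 2))
        out = whisk_step(cmd, 1, params.sample_dt, params)
        np.testing.assert_allclose(out.theta_base, 120.0)

    def test_step_response_time_constant(self, params):
        """After one time constant the Euler lag closes ~1/e of the gap."""
        amps = np.tile(params.amplitudes, 2)
        cmd = WhiskerCommand(np.full(14, 150.0), np.full(14, 100.0), amps)
        n = int(round(params.whisk_tau / params.sample_dt))
        for _ in range(n):
            cmd = whisk_step(cmd, 1, params.sample_dt, params)
        gap = 150.0 - cmd.theta_base[0]
        a = 1.0 - params.sample_dt / params.whisk_tau
        expected_gap = 50.0 * a ** n            # Euler discretisation of exp
        assert gap == pytest.approx(expected_gap, rel=1e-9)
        assert expected_gap / 50.0 == pytest.approx(np.exp(-1.0), abs=0.1)

    def test_retraction_target_is_max_minus_amplitude(self, params):
        amps = np.tile(params.amplitudes, 2)
        cmd = WhiskerCommand(np.full(14, 140.0), np.full(14, 140.0), amps)
        np.testing.assert_allclose(cmd.theta_ret, 140.0 - amps)
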