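import numpy as np
import pytest
from scipy import stats

from vibrisim import attention
from vibrisim.attention import (GridSpec, IORMemory, NoiseState, deposit_blobs,
                                inhibition, ior_field, ior_step,
                                obstacle_inhibition, other_input, remap_field,
                                salience, select_channel, update_excitation)
from vibrisim.params import ObstacleSpec, Params
from vibrisim.plane import FrameTransform, HeadPose, pack_obstacles


class TestDeposit:
    def test_no_points_no_change(self, grid):
        f = grid.zeros()
        out = deposit_blobs(grid, f, np.empty((0, 2)), np.empty(0), 8.0)
        np.testing.assert_array_equal(out, f)

    def test_unit_amplitude_peaks_at_one(self, grid):
        c = grid.cell_center(10, 30)
        out = deposit_blobs(grid, grid.zeros(), np.array([c]),
                            np.array([1.0]), 8.0)
        assert out[10, 30] == pytest.approx(1.0)

    def test_coincident_blobs_clip_at_one(self, grid):
        c = grid.cell_center(10, 30)
        out = deposit_blobs(grid, grid.zeros(), np.array([c, c]),
                            np.array([0.6, 0.6]), 8.0)
        assert out[10, 30] == pytest.approx(1.0)
        assert out.max() <= 1.0

    def test_out_of_extent_points_ignored(self, grid):
        out = deposit_blobs(grid, grid.zeros(), np.array([[500.0, 500.0]]),
                            np.array([1.0]), 8.0)
        assert out.max() == 0.0


class TestRemap:
    def test_identity_for_equal_poses(self, grid, pose0):
        f = grid.zeros()
        f[10, 20] = 0.7
        out = remap_field(grid, f, pose0, pose0)
        np.testing.assert_array_equal(out, f)

    def test_translation_moves_content_world_fixed(self, grid, params, pose0):
        """A translated head sees an impulse at the same world location."""
        f = grid.zeros()
        ix, iy = 25, 45
        f[ix, iy] = 1.0
        world = FrameTransform(pose0).world_from_head(grid.cell_center(ix, iy))
        pose1 = HeadPose(fovea=pose0.fovea + [10.0, 0.0],
                         neck=pose0.neck + [10.0, 0.0])
        out = remap_field(grid, f, pose0, pose1)
        j = np.unravel_index(np.argmax(out), out.shape)
        got_world = FrameTransform(pose1).world_from_head(grid.cell_center(*j))
        assert np.linalg.norm(got_world - world) <= grid.cell * np.sqrt(2)

    def test_rotation_moves_content_world_fixed(self, grid, pose0):
        f = grid.zeros()
        ix, iy = 30, 40
        f[ix, iy] = 1.0
        world = FrameTransform(pose0).world_from_head(grid.cell_center(ix, iy))
        b = np.deg2rad(25.0)
        pose1 = HeadPose(fovea=pose0.fovea,
                         neck=pose0.fovea - 50.0 * np.array([np.cos(b),
                                                             np.sin(b)]))
        out = remap_field(grid, f, pose0, pose1)
        j = np.unravel_index(np.argmax(out), out.shape)
        got_world = FrameTransform(pose1).world_from_head(grid.cell_center(*j))
        assert np.linalg.norm(got_world - world) <= 2 * grid.cell

    def test_mass_non_increasing_under_repeated_rotation(self, grid, pose0):
        f = deposit_blobs(grid, grid.zeros(),
                          np.array([grid.cell_center(22, 31)]),
                          np.array([0.8]), 16.0)
        total = f.sum()
        pose_prev = pose0
        for k in range(1, 11):
            b = np.deg2rad(2.0 * k)
            pose = HeadPose(fovea=pose0.fovea,
                            neck=pose0.fovea - 50.0 * np.array([np.cos(b),
                                                                np.sin(b)]))
            f = remap_field(grid, f, pose_prev, pose)
            pose_prev = pose
        assert f.sum() <= total + 1e-9


class TestNoise:
    def test_unit_stationary_variance(self, grid, params):
        ns = NoiseState.create(grid, params)
        rng = np.random.default_rng(0)
        for _ in range(200):           # warm past the transient
            ns.step(rng)
        samples = [ns.step(rng).copy() for _ in range(300)]
        var = np.var(np.stack(samples))
        assert var == pytest.approx(1.0, rel=0.1)

    def test_mirror_flag_flips_laterally(self, grid, params):
        ns1 = NoiseState.create(grid, params)
        ns2 = NoiseState.create(grid, params)
        f1 = ns1.step(np.random.default_rng(5))
        f2 = ns2.step(np.random.default_rng(5), mirror=True)
        np.testing.assert_array_equal(f1[:, ::-1], f2)


class TestExcitation:
    def test_static_pose_no_noise_is_fixed_point(self, grid, pose0):
        E = grid.zeros()
        E[12, 20] = 0.5
        out = update_excitation(grid, E, grid.zeros(), pose0, pose0,
                                grid.zeros(), 0.0)
        np.testing.assert_array_equal(out, E)

    def test_input_blob_wins_max(self, grid, pose0):
        E = grid.zeros()
        E[12, 20] = 0.3
        I = grid.zeros()
        I[12, 20] = 0.9
        out = update_excitation(grid, E, I, pose0, pose0, grid.zeros(), 0.0)
        assert out[12, 20] == pytest.approx(0.9)

    def test_bounded_in_unit_interval(self, grid, params, pose0):
        rng = np.random.default_rng(2)
        ns = NoiseState.create(grid, params)
        E = grid.zeros()
        for _ in range(50):
            E = update_excitation(grid, E, grid.zeros(), pose0, pose0,
                                  ns.step(rng), params.noise_gain)
        assert E.min() >= 0.0 and E.max() <= 1.0


class TestOtherInput:
    def test_silent_between_ticks(self, grid, params):
        out = other_input(grid, False, np.random.default_rng(0), params)
        assert not out.any()

    def test_single_blob_with_reference_gain(self, grid, params):
        out = other_input(grid, True, np.random.default_rng(3), params)
        assert out.max() == pytest.approx(params.other_gain, abs=0.01)
        # one connected active region
        from scipy import ndimage
        _, n = ndimage.label(out > 0.05)
        assert n == 1

    def test_locations_uniform_over_extent(self, grid, params):
        """Chi-square on a 4x4 occupancy of 1000 sampled peak locations."""
        rng = np.random.default_rng(7)
        counts = np.zeros((4, 4))
        for _ in range(1000):
            f = other_input(grid, True, rng, params)
            ix, iy = np.unravel_index(np.argmax(f), f.shape)
            counts[min(ix * 4 // grid.nx, 3), min(iy * 4 // grid.ny, 3)] += 1
        chi2 = ((counts - 1000 / 16.0) ** 2 / (1000 / 16.0)).sum()
        assert stats.chi2.sf(chi2, 15) > 0.01

    def test_disallowed_cells_avoided(self, grid, params):
        allowed = np.zeros(grid.shape, bool)
        allowed[:, : grid.ny // 4] = True     # only the rightmost strip
        rng = np.random.default_rng(1)
        for _ in range(20):
            f = other_input(grid, True, rng, params, allowed=allowed)
            ix, iy = np.unravel_index(np.argmax(f), f.shape)
            assert allowed[ix, iy]


class TestInhibition:
    def test_no_obstacles_all_zero(self, grid, pose0):
        out = obstacle_inhibition(grid, pack_obstacles([]), pose0)
        assert not out.any()

    def test_inside_and_shadow(self, grid, pose0):
        wall = pack_obstacles([ObstacleSpec(cx_mm=30.0, cy_mm=0.0,
                                            width_mm=10.0, height_mm=60.0)])
        out = obstacle_inhibition(grid, wall, pose0)
        c_in = out[np.argmin(np.abs(grid.xs - 30.0)),
                   np.argmin(np.abs(grid.ys - 0.0))]
        c_behind = out[np.argmin(np.abs(grid.xs - 39.0)),
                       np.argmin(np.abs(grid.ys - 0.0))]
        c_free = out[np.argmin(np.abs(grid.xs - 0.0)),
                     np.argmin(np.abs(grid.ys - 50.0))]
        assert c_in == 1.0 and c_behind == 1.0 and c_free == 0.0

    def test_ior_memory_expiry(self, params):
        mem = IORMemory()
        mem = ior_step(mem, np.array([0.0, 0.0]), 0.0, params)
        mem = ior_step(mem, np.array([10.0, 0.0]), 4.01, params)
        assert len(mem.points) == 1          # the 0 s entry expired
        np.testing.assert_allclose(mem.points[0], [10.0, 0.0])

    def test_ior_field_empty_memory(self, grid, params, pose0):
        assert not ior_field(grid, IORMemory(), pose0, params).any()

    def test_ior_blobs_sum_before_cap(self, grid, params, pose0):
        p = FrameTransform(pose0).world_from_head(grid.cell_center(20, 30))
        mem = IORMemory(points=[p.copy(), p.copy()], times=[0.0, 0.0])
        f = ior_field(grid, mem, pose0, params)
        assert f[20, 30] == pytest.approx(2 * params.ior_gain, abs=1e-6)

    def test_ior_cap(self, grid, params):
        H_ior = np.full(grid.shape, 1.0)
        H = inhibition(grid.zeros(), H_ior, params)
        assert np.all(H == pytest.approx(params.ior_max))

    def test_obstacle_dominates_cap(self, grid, params):
        H = inhibition(np.ones(grid.shape), np.ones(grid.shape), params)
        assert np.all(H == 1.0)


class TestSalience:
    def test_hadamard_gating(self, grid):
        E = np.full(grid.shape, 0.8)
        H = np.full(grid.shape, 0.66)
        S = salience(E, H)
        assert S[0, 0] == pytest.approx(0.272)
        np.testing.assert_array_equal(salience(E, np.ones(grid.shape)),
                                      np.zeros(grid.shape))
        np.testing.assert_array_equal(salience(E, np.zeros(grid.shape)), E)

    def test_channel_selection(self, grid):
        hi = grid.zeros()
        hi[3, 3] = 0.9
        lo = grid.zeros()
        lo[5, 5] = 0.5
        assert select_channel(hi, lo, "other") == "tactile"
        assert select_channel(lo, hi, "other") == "other"
        z = grid.zeros()
        assert select_channel(z, z, "tactile") == "tactile"
        assert select_channel(z, z, "other") == "other"
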