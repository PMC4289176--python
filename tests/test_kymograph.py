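"""Volumetric kymograph: binning, conservation, overlays, projections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurokym import kymograph, synth
from neurokym.exceptions import AlignmentError, DegenerateAxisError
from neurokym.io import ImageStack4D, Track


def stack_from(volumes, voxel=1.0, channels=1):
    arr = np.asarray(volumes)
    if arr.ndim == 4:
        arr = arr[:, None]
    return ImageStack4D(arr, (voxel, voxel, voxel), 1.0)


def plus_x_axis(origin=(0.0, 0.0, 0.0)):
    return kymograph.MigrationAxis(np.asarray(origin), np.array([1.0, 0.0, 0.0]))


class TestMigrationAxis:
    def test_unit_vector_from_two_points(self):
        axis = kymograph.migration_axis(
            np.ones((1, 1, 1), dtype=bool), (1, 1, 1),
            soma_centroid_um=(0, 0, 0), tip_um=(30, 40, 0))
        assert axis.direction == pytest.approx([0.6, 0.8, 0.0])
        assert np.linalg.norm(axis.direction) == pytest.approx(1.0, abs=1e-9)

    def test_coincident_points_error(self):
        with pytest.raises(DegenerateAxisError):
            kymograph.migration_axis(np.ones((1, 1, 1), dtype=bool), (1, 1, 1),
                                     soma_centroid_um=(1, 2, 3), tip_um=(1, 2, 3))

    def test_auto_axis_close_to_truth(self, clean_scene, clean_mask):
        stack, truth = clean_scene
        axis = kymograph.migration_axis(clean_mask.masks[0], stack.voxel_size_um)
        cosang = float(np.dot(axis.direction, truth.axis_direction))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 5.0


class TestVolumetricKymograph:
    def test_single_voxel_lands_in_floor_bin(self):
        vol = np.zeros((1, 1, 8))
        vol[0, 0, 2] = 7.0  # voxel centre x = 2 um; origin -0.5 -> s = 2.5 x bin width
        stack = stack_from([vol])
        mask = vol[None] > 0
        axis = plus_x_axis(origin=(-0.5, 0.0, 0.0))
        for stat in ("sum", "max"):
            kym = kymograph.volumetric_kymograph(stack, 0, mask, axis, stat)
            assert kym.matrix.shape == (1, 1)
            assert kym.bin0_offset_um == pytest.approx(2.0)  # bin index 2
            assert kym.matrix[0, 0] == 7.0

    def test_sum_and_max_on_known_cross_section(self):
        vol = np.zeros((3, 1, 1))
        vol[:, 0, 0] = [1.0, 2.0, 3.0]  # one cross-section, three z voxels
        stack = stack_from([vol])
        mask = np.ones((1, 3, 1, 1), dtype=bool)
        axis = plus_x_axis()
        assert kymograph.volumetric_kymograph(stack, 0, mask, axis, "sum"
                                              ).matrix[0, 0] == 6
        assert kymograph.volumetric_kymograph(stack, 0, mask, axis, "max"
                                              ).matrix[0, 0] == 3

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_sum_columns_match_brute_force_voxel_loop(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.integers(0, 100, size=(4, 8, 8))
        mask = rng.random((1, 4, 8, 8)) < 0.5
        mask[0, 0, 0, 0] = True
        stack = stack_from([vol])
        origin = rng.uniform(-2, 2, size=3)
        direction = rng.normal(size=3)
        axis = kymograph.MigrationAxis(origin, direction)
        kym = kymograph.volumetric_kymograph(stack, 0, mask, axis, "sum")
        # independent voxel loop
        expected = {}
        for z in range(4):
            for y in range(8):
                for x in range(8):
                    if mask[0, z, y, x]:
                        s = np.dot([x - origin[0], y - origin[1], z - origin[2]],
                                   axis.direction)
                        expected[int(np.floor(s))] = (
                            expected.get(int(np.floor(s)), 0) + vol[z, y, x])
        for b, total in expected.items():
            assert kym.matrix[int(round(b - kym.bin0_offset_um)), 0] == total
        assert kym.matrix[:, 0].sum() == vol[mask[0]].sum()

    def test_sum_conservation_exact_for_integer_scene(self, clean_scene, clean_mask):
        stack, truth = clean_scene
        data = np.rint(stack.data).astype(np.int64)
        istack = ImageStack4D(data, stack.voxel_size_um, stack.frame_interval_s,
                              stack.channel_labels)
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        kym = kymograph.volumetric_kymograph(istack, "actin", clean_mask, axis, "sum")
        for ti in range(istack.n_frames):
            assert kym.matrix[:, ti].sum() == data[ti, 2][clean_mask.masks[ti]].sum()

    def test_max_columns_bounded_by_frame_max(self, clean_scene, clean_mask):
        stack, truth = clean_scene
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        kym = kymograph.volumetric_kymograph(stack, "actin", clean_mask, axis, "max")
        for ti in range(stack.n_frames):
            assert kym.matrix[:, ti].max() <= stack.data[ti, 2][clean_mask.masks[ti]].max()
        assert kym.empty.shape == kym.matrix.shape

    def test_constant_speed_scene_shifts_toward_higher_bins(self):
        cfg = synth.SceneConfig(shape=(8, 13, 48, 160), lead_amplitude_um=0.0,
                                nucleus_speed_um_s=0.01,
                                poisson_noise=False, read_noise_sigma=0.0)
        stack, truth = synth.render_scene(cfg)
        mask = np.ones((stack.n_frames,) + stack.shape_zyx, dtype=bool)
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        kym = kymograph.volumetric_kymograph(stack, "nucleus", mask, axis, "sum")
        centers = kym.bin_centers_um()
        com = [(centers * kym.matrix[:, t]).sum() / kym.matrix[:, t].sum()
               for t in range(stack.n_frames)]
        assert np.all(np.diff(com) > 0)

    def test_shape_mismatch_errors(self, clean_scene):
        stack, truth = clean_scene
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        with pytest.raises(AlignmentError):
            kymograph.volumetric_kymograph(
                stack, 0, np.ones((2, 3, 4, 5), dtype=bool), axis)


class TestSomaOverlay:
    def test_spherical_nucleus_projection(self):
        # sphere radius 3 um centred at x = 10 um, voxel 0.25 um
        Z = (np.arange(28) * 0.25)[:, None, None]
        Y = (np.arange(28) * 0.25)[None, :, None]
        X = (np.arange(80) * 0.25)[None, None, :]
        r = np.sqrt((X - 10) ** 2 + (Y - 3.5) ** 2 + (Z - 3.5) ** 2)
        vol = np.where(r <= 3.0, 100.0, 0.0)
        stack = stack_from([vol], voxel=0.25)
        mask = np.ones((1, 28, 28, 80), dtype=bool)
        soma = kymograph.soma_overlay(stack, 0, mask, plus_x_axis(),
                                      margin_um=0.0, threshold=50.0)
        assert soma.loc[0, "s_min"] == pytest.approx(7.0, abs=0.25)
        assert soma.loc[0, "s_center"] == pytest.approx(10.0, abs=0.125)
        assert soma.loc[0, "s_max"] == pytest.approx(13.0, abs=0.25)

    def test_empty_nucleus_channel_flags_all_frames(self):
        stack = stack_from(np.zeros((3, 2, 4, 4)))
        mask = np.ones((3, 2, 4, 4), dtype=bool)
        soma = kymograph.soma_overlay(stack, 0, mask, plus_x_axis())
        assert soma["flagged"].all()
        assert soma["s_center"].isna().all()

    def test_center_tracks_ground_truth_nucleus(self, clean_scene, clean_mask):
        stack, truth = clean_scene
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        soma = kymograph.soma_overlay(stack, "nucleus", clean_mask, axis)
        true_s = axis.project(truth.nucleus_um)
        assert not soma["flagged"].any()
        assert np.abs(soma["s_center"].to_numpy() - true_s).max() < 0.5

    def test_width_mode_brackets_the_soma(self, clean_scene, clean_mask):
        stack, truth = clean_scene
        axis = kymograph.MigrationAxis(truth.axis_origin_um, truth.axis_direction)
        soma = kymograph.soma_overlay(stack, None, clean_mask, axis, mode="width")
        true_s = axis.project(truth.nucleus_um)
        inside = ((soma["s_min"].to_numpy() <= true_s)
                  & (true_s <= soma["s_max"].to_numpy()))
        assert inside.all()


class TestProjectTrack:
    def test_origin_and_displacement(self):
        axis = kymograph.MigrationAxis(np.array([1.0, 2.0, 3.0]),
                                       np.array([0.0, 1.0, 0.0]))
        tr = Track("t", "c", np.array([0, 1]),
                   np.array([[1.0, 2.0, 3.0], [1.0, 7.0, 3.0]]))
        s = kymograph.project_track(tr, axis)
        assert s.loc[0] == pytest.approx(0.0)
        assert s.loc[1] == pytest.approx(5.0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_matches_brute_force_dot_products(self, seed):
        rng = np.random.default_rng(seed)
        axis = kymograph.MigrationAxis(rng.normal(size=3), rng.normal(size=3))
        pos = rng.normal(size=(6, 3)) * 10
        tr = Track("t", "c", np.arange(0, 12, 2), pos)
        s = kymograph.project_track(tr, axis)
        for f, p in zip(tr.frames, pos):
            assert s.loc[f] == pytest.approx(
                float(np.dot(p - axis.origin_um, axis.direction)), abs=1e-9)
        assert 1 not in s.index  # absent frames yield no value
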