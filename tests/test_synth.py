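"""Generator contracts: kinematics, rendering, noise, FRAP traces."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurokym import synth
from neurokym.exceptions import GeometryError, InvalidConfigError


def cfg(**kw):
    base = dict(poisson_noise=False, read_noise_sigma=0.0)
    base.update(kw)
    return synth.SceneConfig(**base)


class TestTwoStrokeTrajectory:
    def test_zero_motion_gives_constant_series(self):
        traj = synth.two_stroke_trajectory(cfg(nucleus_speed_um_s=0.0,
                                               lead_amplitude_um=0.0))
        assert np.all(traj.nucleus_um == traj.nucleus_um[0])
        assert np.all(traj.organelle_um == traj.organelle_um[0])

    def test_constant_speed_mode_step_length(self):
        c = cfg(lead_amplitude_um=0.0, nucleus_speed_um_s=0.01)
        traj = synth.two_stroke_trajectory(c)
        steps = np.diff(traj.nucleus_um)
        assert steps == pytest.approx(0.01 * c.frame_interval_s, abs=1e-12)

    def test_drug_factor_scales_step_ratio_exactly(self):
        c = cfg(lead_amplitude_um=0.0, nucleus_speed_um_s=0.01,
                shape=(31, 13, 48, 160), drug_time_s=24 * 60.0,
                post_drug_factor=0.25)
        traj = synth.two_stroke_trajectory(c)
        starts = traj.times_s[:-1]
        steps = np.diff(traj.nucleus_um)
        pre = steps[starts < c.drug_time_s].mean()
        post = steps[starts >= c.drug_time_s].mean()
        assert post / pre == pytest.approx(0.25, abs=1e-9)

    def test_organelle_always_leads(self):
        traj = synth.two_stroke_trajectory(cfg())
        assert np.all(traj.organelle_um - traj.nucleus_um >= -1e-12)

    @given(v=st.floats(0.001, 0.05), period_frames=st.integers(2, 10))
    @settings(deadline=None, max_examples=25)
    def test_per_cycle_nucleus_advance(self, v, period_frames):
        dt = 60.0
        c = cfg(shape=(3 * period_frames + 1, 13, 48, 160),
                frame_interval_s=dt, nucleus_speed_um_s=v,
                cycle_period_s=period_frames * dt, lead_amplitude_um=2.0)
        traj = synth.two_stroke_trajectory(c)
        advance = traj.nucleus_um[period_frames] - traj.nucleus_um[0]
        assert advance == pytest.approx(v * c.cycle_period_s, abs=1e-9)

    @pytest.mark.parametrize("bad", [
        dict(frame_interval_s=0.0),
        dict(cycle_period_s=-5.0),
        dict(cycle_period_s=100.0, frame_interval_s=60.0),  # < 2 x interval
        dict(post_drug_factor=1.5),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(InvalidConfigError):
            synth.two_stroke_trajectory(cfg(**bad))


class TestRenderScene:
    def test_static_scene_frames_identical(self):
        stack, _ = synth.render_scene(cfg(nucleus_speed_um_s=0.0,
                                          lead_amplitude_um=0.0))
        assert np.array_equal(stack.data, np.broadcast_to(
            stack.data[:1], stack.data.shape))

    def test_organelle_centroid_matches_truth(self, clean_scene):
        stack, truth = clean_scene
        from neurokym.io import voxel_centers_um
        Z, Y, X = voxel_centers_um(stack.shape_zyx, stack.voxel_size_um)
        tol = 0.5 * max(stack.voxel_size_um)
        for ti in range(stack.n_frames):
            w = stack.data[ti, 1]
            centroid = np.array([(w * X).sum(), (w * Y).sum(), (w * Z).sum()]) / w.sum()
            assert np.abs(centroid - truth.organelle_um[ti]).max() < tol

    def test_seed_changes_voxels_not_truth(self):
        c1 = synth.SceneConfig(seed=1)
        c2 = synth.SceneConfig(seed=2)
        s1, t1 = synth.render_scene(c1)
        s2, t2 = synth.render_scene(c2)
        assert np.array_equal(t1.nucleus_um, t2.nucleus_um)
        assert np.array_equal(t1.compartment_fractions, t2.compartment_fractions)
        assert not np.array_equal(s1.data, s2.data)

    def test_same_seed_is_byte_identical(self):
        s1, _ = synth.render_scene(synth.SceneConfig(seed=5))
        s2, _ = synth.render_scene(synth.SceneConfig(seed=5))
        assert s1.data.tobytes() == s2.data.tobytes()

    def test_actin_total_conserved_across_frames(self, clean_scene):
        stack, _ = clean_scene
        totals = stack.data[:, 2].sum(axis=(1, 2, 3))
        assert np.ptp(totals) / totals[0] < 1e-3

    def test_adhesion_channel_fixed_in_lab_frame(self, clean_scene):
        stack, _ = clean_scene
        ch3 = stack.data[:, 3]
        assert np.array_equal(ch3, np.broadcast_to(ch3[:1], ch3.shape))

    def test_out_of_field_cell_names_first_bad_frame(self):
        c = cfg(shape=(13, 13, 48, 80))  # 20 um of x for a ~25 um journey
        with pytest.raises(GeometryError, match="frame"):
            synth.render_scene(c)

    def test_metadata_carried(self, clean_scene, clean_config):
        stack, _ = clean_scene
        assert stack.voxel_size_um == clean_config.voxel_size_um
        assert stack.frame_interval_s == clean_config.frame_interval_s
        assert stack.channel_labels == synth.CHANNELS

    def test_config_dict_round_trip(self, clean_config):
        doc = clean_config.to_dict()
        assert synth.SceneConfig.from_dict(doc) == clean_config
        with pytest.raises(InvalidConfigError, match="unknown"):
            synth.SceneConfig.from_dict({"not_a_key": 1})


class TestGroundTruth:
    def test_positions_inside_rendered_cell(self, clean_scene, clean_config):
        _, truth = clean_scene
        c = clean_config
        rel = truth.organelle_um[:, 0] - truth.nucleus_um[:, 0]
        assert np.all(rel >= -1e-12)
        assert np.all(rel <= c.process_length_um)

    def test_soma_interval_is_radius_around_nucleus(self, clean_scene, clean_config):
        _, truth = clean_scene
        width = truth.soma_interval_um[:, 1] - truth.soma_interval_um[:, 0]
        assert width == pytest.approx(2 * clean_config.soma_radius_um)

    def test_truth_serializes_to_json(self, clean_scene, tmp_path):
        from neurokym.io import dump_json
        _, truth = clean_scene
        dump_json(truth.to_dict(), tmp_path / "gt.json")
        assert (tmp_path / "gt.json").stat().st_size > 0


class TestConstantSpeedTracks:
    def test_step_length_exact_without_noise(self):
        tracks = synth.constant_speed_tracks(3, 0.01, 120.0, 1440.0, seed=0)
        for tr in tracks:
            steps = np.linalg.norm(np.diff(tr.positions_um, axis=0), axis=1)
            assert steps == pytest.approx(0.01 * 120.0, abs=1e-12)

    def test_directed_mode_is_straight(self):
        (tr,) = synth.constant_speed_tracks(1, 0.02, 15.0, 300.0,
                                            mode="directed", seed=3)
        net = np.linalg.norm(tr.positions_um[-1] - tr.positions_um[0])
        assert net == pytest.approx(0.02 * 300.0, abs=1e-9)

    def test_bad_mode_rejected(self):
        with pytest.raises(InvalidConfigError):
            synth.constant_speed_tracks(1, 0.01, 15.0, 300.0, mode="spiral")


class TestFrapTrace:
    def test_first_sample_is_bleach_floor(self):
        tr = synth.generate_frap_trace(0.1, 0.8, pre_level=100, bleach_depth=80)
        assert tr.intensity[0] == pytest.approx(20.0, abs=1e-12)

    def test_full_recovery_reaches_pre_level(self):
        k = 0.5
        tr = synth.generate_frap_trace(k, 1.0, pre_level=100, bleach_depth=80,
                                       interval_s=1.0, duration_s=20.0 / k)
        assert tr.intensity[-1] == pytest.approx(100.0, abs=1e-6)

    def test_half_life_midpoint(self):
        k = np.log(2) / 10.0
        tr = synth.generate_frap_trace(k, 0.9, pre_level=100, bleach_depth=80,
                                       interval_s=2.0, duration_s=60.0)
        mid = 0.5 * (tr.truth.post_level + tr.truth.plateau)
        assert tr.intensity[5] == pytest.approx(mid, abs=1e-12)  # t = 10 s
        assert tr.truth.t_half_s == pytest.approx(np.log(2) / k, abs=1e-12)

    @pytest.mark.parametrize("kw", [
        dict(k_per_s=-1.0, mobile_fraction=0.5),
        dict(k_per_s=0.1, mobile_fraction=1.5),
        dict(k_per_s=0.1, mobile_fraction=0.5, bleach_depth=0.0),
        dict(k_per_s=0.1, mobile_fraction=0.5, interval_s=-2.0),
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(InvalidConfigError):
            synth.generate_frap_trace(**kw)

    def test_seeded_noise_reproducible(self):
        a = synth.generate_frap_trace(0.1, 0.9, noise_sigma=2.0, seed=4)
        b = synth.generate_frap_trace(0.1, 0.9, noise_sigma=2.0, seed=4)
        assert np.array_equal(a.intensity, b.intensity)


def test_analytic_volume_against_numeric_occupancy():
    """Union-of-solids volume matches a brute-force occupancy integral."""
    c = cfg()
    from neurokym.io import voxel_centers_um
    Z, Y, X = voxel_centers_um((40, 60, 180), (0.25, 0.25, 0.25))
    d = synth._cell_distance(Z, Y, X, (12.0, 7.5, 5.0), c)
    numeric = (d <= 0).sum() * 0.25 ** 3
    assert numeric == pytest.approx(synth.analytic_cell_volume_um3(c), rel=0.02)
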