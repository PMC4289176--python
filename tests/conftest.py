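import numpy as np
import pytest
from hypothesis import settings

from neurokym import segmentation, synth

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def voxel_index(point_um, spacing_zyx):
    """Physical (x, y, z) um -> nearest voxel index (z, y, x)."""
    dz, dy, dx = spacing_zyx
    x, y, z = point_um
    return (int(round(z / dz)), int(round(y / dy)), int(round(x / dx)))


@pytest.fixture(scope="session")
def clean_config():
    """Default migrating-neuron scene with noise disabled."""
    return synth.SceneConfig(poisson_noise=False, read_noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_scene(clean_config):
    return synth.render_scene(clean_config)


@pytest.fixture(scope="session")
def clean_mask(clean_scene, clean_config):
    """Actin-channel segmentation of the clean scene at half the plateau."""
    stack, truth = clean_scene
    seed = voxel_index(truth.nucleus_um[0], stack.spacing_zyx)
    seeds = [seed] + [None] * (stack.n_frames - 1)
    return segmentation.segment_sequence(
        stack, "actin", clean_config.actin_baseline / 2, seeds)


@pytest.fixture(scope="session")
def handover_scene():
    """Constant-speed neuron sliding past three lab-frame adhesion puncta.

    The near-uniform process half-width and tight PSF keep each punctum's
    masked weight constant while the soma traverses it, so the computed
    compartment fractions hand over strictly monotonically.
    """
    cfg = synth.SceneConfig(
        shape=(13, 13, 40, 200), trailing_length_um=12.0,
        taper_halfwidth_um=(1.5, 1.5), nucleus_speed_um_s=16.0 / 1440.0,
        lead_amplitude_um=0.0,
        adhesion_positions_um=(18.0, 21.0, 24.0),
        adhesion_amplitudes=(200.0, 200.0, 200.0),
        adhesion_sigma_um=0.3, psf_sigma_um=(0.2, 0.2, 0.3),
        poisson_noise=False, read_noise_sigma=0.0)
    stack, truth = synth.render_scene(cfg)
    seed = voxel_index(truth.nucleus_um[0], stack.spacing_zyx)
    mask = segmentation.segment_sequence(
        stack, "actin", cfg.actin_baseline / 2,
        [seed] + [None] * (stack.n_frames - 1))
    return cfg, stack, truth, mask


def soma_intervals_from_truth(truth):
    """Project the ground-truth soma interval onto the migration axis."""
    from neurokym.kymograph import MigrationAxis
    axis = MigrationAxis(truth.axis_origin_um, truth.axis_direction)
    y = truth.nucleus_um[:, 1]
    z = truth.nucleus_um[:, 2]
    lo = axis.project(np.stack([truth.soma_interval_um[:, 0], y, z], axis=1))
    hi = axis.project(np.stack([truth.soma_interval_um[:, 1], y, z], axis=1))
    return axis, np.stack([lo, hi], axis=1)
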