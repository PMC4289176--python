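"""Synthetic migrating-neuron scenes, tracks, and FRAP traces.

The generator emulates the statistical structure the downstream analysis
assumes for a cerebellar granule neuron migrating along a glial fiber:

* a soma (soft sphere) with a tapered leading process, translating
  rigidly along +x;
* two-stroke kinematics: the organelle (Golgi / primary cilium punctum)
  advances during the first half of each cycle, the nucleus follows in
  the second half, so the organelle always leads;
* an actin channel with a proximal-leading-process hotspot;
* adhesion puncta fixed in the laboratory frame that the soma slides past;
* an optional drug-addition time after which all step sizes shrink by a
  constant factor;
* single-exponential FRAP recovery traces.

Everything is rendered from smooth analytic fields evaluated at voxel
centres (Gaussian blobs; sigmoid-softened solids), so the rendered cell
translates rigidly and total channel intensity is conserved to grid
precision.  Ground truth for every quantity the pipeline estimates is
returned alongside the images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import GeometryError, InvalidConfigError
from .io import ImageStack4D, Track, Wall, voxel_centers_um

CHANNELS = ["nucleus", "organelle", "actin", "adhesion"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SceneConfig:
    """Parameters of one synthetic migration scene.

    Defaults mirror the acquisition geometry of the assays the pipeline is
    built for: 13 z-sections spanning 10 um, 0.25 um x-y pixels, 2-minute
    frames over 24 minutes, and a soma translocating at 0.009 um/s.
    """

    # grid
    shape: tuple[int, int, int, int] = (13, 13, 48, 160)  # (t, z, y, x)
    voxel_size_um: tuple[float, float, float] = (0.25, 0.25, 10.0 / 12.0)  # (x, y, z)
    frame_interval_s: float = 120.0
    # cell geometry (um)
    soma_radius_um: float = 2.5
    nucleus_radius_um: float = 2.0
    process_length_um: float = 15.0
    trailing_length_um: float = 6.0
    taper_halfwidth_um: tuple[float, float] = (1.5, 0.4)  # (base, tip)
    start_position_um: tuple[float, float, float] | None = None  # (x, y, z)
    # kinematics
    nucleus_speed_um_s: float = 0.009
    lead_amplitude_um: float = 5.0
    cycle_period_s: float = 1200.0
    drug_time_s: float | None = None
    post_drug_factor: float = 1.0
    # intensities
    actin_baseline: float = 100.0
    hotspot_amplitude: float = 150.0
    hotspot_sigma_um: float = 1.0
    hotspot_offset_um: float = 4.0
    hotspot_track_organelle: bool = False
    nucleus_amplitude: float = 200.0
    organelle_amplitude: float = 300.0
    organelle_sigma_um: float = 0.4
    adhesion_positions_um: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0)
    adhesion_amplitudes: tuple[float, ...] = (200.0, 200.0, 200.0, 200.0)
    adhesion_sigma_um: float = 0.4
    # optics + noise
    psf_sigma_um: tuple[float, float, float] = (0.3, 0.3, 0.8)  # (x, y, z)
    edge_softness_um: float = 0.5
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 4 or min(self.shape) < 1:
            raise InvalidConfigError(f"shape must be 4 positive extents, got {self.shape}")
        for name in ("soma_radius_um", "nucleus_radius_um", "process_length_um",
                     "hotspot_sigma_um", "organelle_sigma_um", "adhesion_sigma_um",
                     "edge_softness_um"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be > 0")
        if any(v <= 0 for v in self.voxel_size_um) or any(v <= 0 for v in self.psf_sigma_um):
            raise InvalidConfigError("voxel sizes and PSF sigmas must be > 0")
        if any(w <= 0 for w in self.taper_halfwidth_um):
            raise InvalidConfigError("taper half-widths must be > 0")
        if self.trailing_length_um < 0:
            raise InvalidConfigError("trailing process length must be >= 0")
        if self.frame_interval_s <= 0:
            raise InvalidConfigError("frame interval must be > 0")
        if self.cycle_period_s <= 0:
            raise InvalidConfigError("cycle period must be > 0")
        if self.nucleus_speed_um_s < 0 or self.lead_amplitude_um < 0:
            raise InvalidConfigError("speeds and amplitudes must be >= 0")
        if not (0.0 <= self.post_drug_factor <= 1.0):
            raise InvalidConfigError("post-drug speed factor must be in [0, 1]")
        if self.lead_amplitude_um > 0 and self.cycle_period_s < 2 * self.frame_interval_s:
            raise InvalidConfigError(
                "cycle period must be >= 2 x frame interval for two-stroke motion"
            )
        if len(self.adhesion_positions_um) != len(self.adhesion_amplitudes):
            raise InvalidConfigError("adhesion positions and amplitudes differ in length")

    # YAML plumbing -----------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "SceneConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise InvalidConfigError(f"unknown scene config keys: {sorted(unknown)}")
        doc = {k: (tuple(v) if isinstance(v, list) else v) for k, v in doc.items()}
        return cls(**doc)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in out.items()}

    # derived geometry ---------------------------------------------------

    def grid_extent_um(self) -> tuple[float, float, float]:
        """Physical position of the last voxel centre along (x, y, z)."""
        _, nz, ny, nx = self.shape[0], self.shape[1], self.shape[2], self.shape[3]
        dx, dy, dz = self.voxel_size_um
        return ((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)

    def start_xyz(self) -> np.ndarray:
        if self.start_position_um is not None:
            return np.asarray(self.start_position_um, dtype=float)
        ex, ey, ez = self.grid_extent_um()
        x0 = max(self.soma_radius_um, self.trailing_length_um) + 2.5
        return np.array([x0, ey / 2.0, ez / 2.0])


class Trajectory(NamedTuple):
    """Paired nucleus/organelle positions along the migration axis (um)."""

    times_s: np.ndarray
    nucleus_um: np.ndarray
    organelle_um: np.ndarray


@dataclass
class GroundTruth:
    """True quantities underlying one rendered scene."""

    times_s: np.ndarray
    nucleus_um: np.ndarray        # (t, 3) (x, y, z)
    organelle_um: np.ndarray      # (t, 3)
    hotspot_um: np.ndarray        # (t, 3)
    soma_interval_um: np.ndarray  # (t, 2) projected (s_min, s_max)
    compartment_fractions: np.ndarray  # (t, 3) (leading, soma, trailing)
    axis_origin_um: np.ndarray    # (3,)
    axis_direction: np.ndarray    # (3,) unit
    velocity_pre_um_s: dict
    velocity_post_um_s: dict | None
    walls: list = field(default_factory=list)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["walls"] = [
            {"vertices": np.asarray(w.vertices).tolist(), "frames": w.frames}
            if isinstance(w, Wall) else w
            for w in self.walls
        ]
        return out


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def two_stroke_trajectory(config: SceneConfig) -> Trajectory:
    """Nucleus and organelle positions along the migration axis.

    With a positive lead amplitude ``A`` the motion follows a square-wave
    two-stroke cycle of period ``P``: the organelle advances during the
    first half-cycle, the nucleus catches up at speed ``2 v`` during the
    second, advancing exactly ``v * P`` per cycle.  The organelle position
    is the constant-speed drift ``v t`` plus a triangular lead of amplitude
    ``A``, so organelle - nucleus >= 0 at all times.  ``A == 0`` selects
    the constant-speed degenerate mode (both objects move at ``v``).

    After ``drug_time_s`` every step is scaled by ``post_drug_factor``.
    Positions start at 0; the renderer adds the scene's start position.
    """
    config.validate()
    n_t = config.shape[0]
    dt = config.frame_interval_s
    v = config.nucleus_speed_um_s
    amp = config.lead_amplitude_um
    per = config.cycle_period_s
    t = np.arange(n_t) * dt

    if amp == 0.0:
        nuc = v * t
        org = v * t
    else:
        t_in = t % per
        phase = t_in / per
        tri = np.where(phase <= 0.5, 2 * phase, 2 * (1 - phase))
        nuc = v * (np.floor(t / per) * per + 2 * np.maximum(0.0, t_in - per / 2))
        org = v * t + amp * tri

    if config.drug_time_s is not None and config.post_drug_factor != 1.0:
        scale = np.where(t[:-1] >= config.drug_time_s, config.post_drug_factor, 1.0)
        nuc = np.concatenate([[nuc[0]], nuc[0] + np.cumsum(np.diff(nuc) * scale)])
        org = np.concatenate([[org[0]], org[0] + np.cumsum(np.diff(org) * scale)])
    return Trajectory(t, nuc, org)


def _phase_speeds(traj: Trajectory, drug_time_s: float | None, dt: float):
    """Mean per-step speed of each series before/after drug addition."""
    def mean_step(series, sel):
        steps = np.abs(np.diff(series))[sel]
        return float(np.mean(steps) / dt) if len(steps) else float("nan")

    starts = traj.times_s[:-1]
    if drug_time_s is None:
        pre = np.ones(len(starts), dtype=bool)
        return ({"nucleus": mean_step(traj.nucleus_um, pre),
                 "organelle": mean_step(traj.organelle_um, pre)}, None)
    pre = starts < drug_time_s
    post = ~pre
    return ({"nucleus": mean_step(traj.nucleus_um, pre),
             "organelle": mean_step(traj.organelle_um, pre)},
            {"nucleus": mean_step(traj.nucleus_um, post),
             "organelle": mean_step(traj.organelle_um, post)})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _tapered_process(Z, Y, X, center_xyz, length, halfwidths, sign):
    """Signed distance to a tapered rod along +x (sign=+1) or -x (sign=-1)."""
    cx, cy, cz = center_xyz
    w_base, w_tip = halfwidths
    s = np.clip(sign * (X - cx), 0.0, length)
    halfwidth = w_base + (w_tip - w_base) * s / length
    radial = np.sqrt((X - cx - sign * s) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    return radial - halfwidth


def _cell_distance(Z, Y, X, center_xyz, cfg: SceneConfig) -> np.ndarray:
    """Approximate signed distance (um) to the cell solid.

    The solid is the union of the soma sphere, a tapered leading process
    along +x and (optionally) a tapered trailing process along -x.
    """
    cx, cy, cz = center_xyz
    d = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2) - cfg.soma_radius_um
    d = np.minimum(d, _tapered_process(Z, Y, X, center_xyz, cfg.process_length_um,
                                       cfg.taper_halfwidth_um, +1))
    if cfg.trailing_length_um > 0:
        d = np.minimum(d, _tapered_process(Z, Y, X, center_xyz,
                                           cfg.trailing_length_um,
                                           cfg.taper_halfwidth_um, -1))
    return d


def _gaussian(Z, Y, X, center_xyz, sigma_xyz) -> np.ndarray:
    cx, cy, cz = center_xyz
    sx, sy, sz = sigma_xyz
    return np.exp(-((X - cx) ** 2 / (2 * sx ** 2)
                    + (Y - cy) ** 2 / (2 * sy ** 2)
                    + (Z - cz) ** 2 / (2 * sz ** 2)))


def analytic_cell_volume_um3(cfg: SceneConfig) -> float:
    """Volume of the soma-sphere U tapered-cone solid, by geometry.

    The process is a cone frustum of length L with radii (w_base, w_tip);
    the part of the frustum inside the soma sphere is removed by brute
    numerical integration of the overlap along x.
    """
    r = cfg.soma_radius_um
    w0, w1 = cfg.taper_halfwidth_um
    total = 4.0 / 3.0 * np.pi * r ** 3

    def frustum_minus_overlap(length):
        frustum = np.pi * length / 3.0 * (w0 ** 2 + w0 * w1 + w1 ** 2)
        # overlap: for x in [0, r], min(cone disk, sphere disk) area
        xs = np.linspace(0, min(r, length), 2049)
        w = w0 + (w1 - w0) * xs / length
        sph = np.sqrt(np.maximum(r ** 2 - xs ** 2, 0.0))
        return frustum - np.trapezoid(np.pi * np.minimum(w, sph) ** 2, xs)

    total += frustum_minus_overlap(cfg.process_length_um)
    if cfg.trailing_length_um > 0:
        total += frustum_minus_overlap(cfg.trailing_length_um)
    return float(total)


def render_scene(config: SceneConfig) -> tuple[ImageStack4D, GroundTruth]:
    """Render a 4-channel scene and its ground truth.

    Channels: 0 nucleus, 1 organelle punctum, 2 actin (baseline cell fill
    plus hotspot), 3 adhesion puncta fixed in the lab frame.  Noise
    (Poisson then additive Gaussian) is applied after geometry.
    """
    config.validate()
    n_t, nz, ny, nx = config.shape
    traj = two_stroke_trajectory(config)
    start = config.start_xyz()
    x0, y0, z0 = start
    nuc_x = x0 + traj.nucleus_um
    org_x = x0 + traj.organelle_um

    ex, ey, ez = config.grid_extent_um()
    w_base = config.taper_halfwidth_um[0]
    half_y = max(config.soma_radius_um, w_base)
    for ti in range(n_t):
        lo_x = nuc_x[ti] - max(config.soma_radius_um, config.trailing_length_um)
        hi_x = nuc_x[ti] + config.process_length_um
        if (lo_x < 0 or hi_x > ex or y0 - half_y < 0 or y0 + half_y > ey
                or z0 - half_y < 0 or z0 + half_y > ez):
            raise GeometryError(
                f"cell leaves the grid at frame {ti}: x span [{lo_x:.2f}, {hi_x:.2f}] um "
                f"vs grid extent {ex:.2f} um"
            )

    Z, Y, X = voxel_centers_um((nz, ny, nx), config.voxel_size_um)
    px, py, pz = config.psf_sigma_um
    pxy = 0.5 * (px + py)

    def blurred(sigma):  # object sigma composed with the PSF, per axis
        return (np.sqrt(sigma ** 2 + px ** 2),
                np.sqrt(sigma ** 2 + py ** 2),
                np.sqrt(sigma ** 2 + pz ** 2))

    soft = config.edge_softness_um
    hot_x = org_x if config.hotspot_track_organelle \
        else nuc_x + config.hotspot_offset_um

    # lab-frame adhesion field is time-invariant: render once
    ch3 = np.zeros((nz, ny, nx))
    for pos, a in zip(config.adhesion_positions_um, config.adhesion_amplitudes):
        ch3 += a * _gaussian(Z, Y, X, (pos, y0, z0), blurred(config.adhesion_sigma_um))

    data = np.zeros((n_t, 4, nz, ny, nx))
    for ti in range(n_t):
        nuc_c = (nuc_x[ti], y0, z0)
        org_c = (org_x[ti], y0, z0)
        occ = _sigmoid(-_cell_distance(Z, Y, X, nuc_c, config) / soft)
        r_n = np.sqrt((X - nuc_c[0]) ** 2 + (Y - y0) ** 2 + (Z - z0) ** 2)
        data[ti, 0] = config.nucleus_amplitude * _sigmoid(
            (config.nucleus_radius_um - r_n) / soft)
        data[ti, 1] = config.organelle_amplitude * _gaussian(
            Z, Y, X, org_c, blurred(config.organelle_sigma_um))
        hot = config.hotspot_amplitude * _gaussian(
            Z, Y, X, (hot_x[ti], y0, z0), blurred(config.hotspot_sigma_um))
        data[ti, 2] = occ * (config.actin_baseline + hot)
        data[ti, 3] = ch3

    rng = np.random.default_rng(config.seed)
    if config.poisson_noise:
        data = rng.poisson(data).astype(float)
    if config.read_noise_sigma > 0:
        data = data + rng.normal(0.0, config.read_noise_sigma, size=data.shape)
        data = np.maximum(data, 0.0)

    stack = ImageStack4D(data, config.voxel_size_um, config.frame_interval_s,
                         list(CHANNELS))

    soma_interval = np.stack([nuc_x - config.soma_radius_um,
                              nuc_x + config.soma_radius_um], axis=1)
    amps = np.asarray(config.adhesion_amplitudes, dtype=float)
    pos = np.asarray(config.adhesion_positions_um, dtype=float)
    fractions = np.zeros((n_t, 3))
    if amps.sum() > 0:
        for ti in range(n_t):
            lo, hi = soma_interval[ti]
            fractions[ti, 0] = amps[pos > hi].sum() / amps.sum()
            fractions[ti, 1] = amps[(pos >= lo) & (pos <= hi)].sum() / amps.sum()
            fractions[ti, 2] = amps[pos < lo].sum() / amps.sum()

    pre, post = _phase_speeds(traj, config.drug_time_s, config.frame_interval_s)
    col = lambda xs: np.stack([xs, np.full(n_t, y0), np.full(n_t, z0)], axis=1)
    truth = GroundTruth(
        times_s=traj.times_s,
        nucleus_um=col(nuc_x),
        organelle_um=col(org_x),
        hotspot_um=col(hot_x),
        soma_interval_um=soma_interval,
        compartment_fractions=fractions,
        axis_origin_um=np.array([nuc_x[0], y0, z0]),
        axis_direction=np.array([1.0, 0.0, 0.0]),
        velocity_pre_um_s=pre,
        velocity_post_um_s=post,
        walls=[],
    )
    return stack, truth


def truth_tracks(truth: GroundTruth) -> list[Track]:
    """Nucleus and organelle ground-truth positions as Track objects."""
    frames = np.arange(len(truth.times_s))
    return [
        Track("nucleus", "nucleus", frames, truth.nucleus_um),
        Track("organelle", "organelle", frames, truth.organelle_um),
    ]


# ---------------------------------------------------------------------------
# synthetic track tables
# ---------------------------------------------------------------------------

def constant_speed_tracks(n_tracks: int, speed_um_s: float, interval_s: float,
                          duration_s: float, noise_sigma_um: float = 0.0,
                          mode: str = "walk", seed: int | None = None,
                          rng: np.random.Generator | None = None,
                          channel: str = "organelle") -> list[Track]:
    """Tracks with fixed per-step speed, for estimator-recovery experiments.

    ``mode='directed'`` uses one random in-plane heading per track
    (a migrating cell); ``mode='walk'`` redraws the heading every step
    (basal random motility).  Gaussian localization noise of the given
    sigma is added to the x and y coordinates of every measured position;
    z is carried noise-free, as for tracking on serial optical sections
    where axial localization is quantized rather than Gaussian.
    """
    if mode not in ("walk", "directed"):
        raise InvalidConfigError(f"mode must be 'walk' or 'directed', got {mode!r}")
    if speed_um_s < 0 or interval_s <= 0 or duration_s <= 0:
        raise InvalidConfigError("speed >= 0 and positive interval/duration required")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s / interval_s))
    frames = np.arange(n_steps + 1)
    step_len = speed_um_s * interval_s
    tracks = []
    for i in range(n_tracks):
        if mode == "directed":
            theta = np.full(n_steps, rng.uniform(0, 2 * np.pi))
        else:
            theta = rng.uniform(0, 2 * np.pi, size=n_steps)
        steps = step_len * np.stack([np.cos(theta), np.sin(theta),
                                     np.zeros(n_steps)], axis=1)
        pos = np.concatenate([[np.zeros(3)], np.cumsum(steps, axis=0)])
        pos = pos + rng.uniform(0, 50.0, size=3)  # arbitrary field position
        if noise_sigma_um > 0:
            pos[:, :2] += rng.normal(0.0, noise_sigma_um, size=(n_steps + 1, 2))
        tracks.append(Track(f"track{i:03d}", channel, frames, pos))
    return tracks


# ---------------------------------------------------------------------------
# FRAP traces
# ---------------------------------------------------------------------------

@dataclass
class FrapGroundTruth:
    k_per_s: float
    t_half_s: float
    mobile_fraction: float
    pre_level: float
    post_level: float
    plateau: float


class FrapTrace(NamedTuple):
    times_s: np.ndarray
    intensity: np.ndarray
    truth: FrapGroundTruth


def generate_frap_trace(k_per_s: float, mobile_fraction: float,
                        pre_level: float = 100.0, bleach_depth: float = 80.0,
                        interval_s: float = 2.0, duration_s: float = 60.0,
                        noise_sigma: float = 0.0, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> FrapTrace:
    """Single-exponential recovery trace after an instantaneous bleach.

    ``I(t) = I_post + (I_plateau - I_post) (1 - exp(-k t))`` with
    ``I_plateau - I_post = mobile_fraction * (I_pre - I_post)``; the first
    sample (t = 0) equals the bleach floor ``I_post`` when noise is off.
    """
    if k_per_s <= 0:
        raise InvalidConfigError(f"recovery rate k must be > 0, got {k_per_s}")
    if not (0.0 <= mobile_fraction <= 1.0):
        raise InvalidConfigError(f"mobile fraction must be in [0, 1], got {mobile_fraction}")
    if bleach_depth <= 0:
        raise InvalidConfigError(f"bleach depth must be > 0, got {bleach_depth}")
    if interval_s <= 0 or duration_s <= 0:
        raise InvalidConfigError("interval and duration must be > 0")
    post = pre_level - bleach_depth
    plateau = post + mobile_fraction * (pre_level - post)
    t = np.arange(0.0, duration_s + 0.5 * interval_s, interval_s)
    intensity = post + (plateau - post) * (1.0 - np.exp(-k_per_s * t))
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sigma, size=t.shape)
    truth = FrapGroundTruth(k_per_s, float(np.log(2) / k_per_s), mobile_fraction,
                            pre_level, post, plateau)
    return FrapTrace(t, intensity, truth)
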