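"""Seeded threshold 3D segmentation with exclusion walls.

A cell is segmented per frame as the 6-connected component of
``{intensity >= threshold}`` that contains a soma seed voxel, after
user-supplied "walls" (polylines extruded through z) have been zeroed
out of the volume.  Because walls are rasterized 8-connected in-plane
and extruded through every section, a one-voxel-thick wall is a
guaranteed separator for 6-connected components, which is what makes
them sufficient to keep a segmentation from bleeding into an adjacent
cell.

The threshold is per-cell and constant over the sequence.  An Otsu
initializer is available but never applied implicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import threshold_otsu

from .exceptions import AlignmentError, GeometryError, SeedError
from .io import ImageStack4D, Wall

#: 6-connectivity structuring element (faces only).
CONNECTIVITY_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationMask:
    """Per-frame boolean voxel sets connected to the soma seed."""

    masks: np.ndarray                  # (t, z, y, x) bool
    threshold: float
    seeds: list[tuple[int, int, int] | None]   # (z, y, x) per frame
    flagged: np.ndarray                # (t,) bool, frames where segmentation failed
    walls: list[Wall] = field(default_factory=list)

    def qc_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.masks.shape[0]),
            "mask_voxels": self.masks.sum(axis=(1, 2, 3)),
            "flagged": self.flagged.astype(bool),
        })


def rasterize_wall(wall: Wall, shape_yx: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """8-connected raster of a wall polyline; returns (rows, cols) pixel indices."""
    ny, nx = shape_yx
    verts = np.rint(wall.vertices).astype(int)
    if (verts[:, 0].min() < 0 or verts[:, 0].max() >= nx
            or verts[:, 1].min() < 0 or verts[:, 1].max() >= ny):
        raise GeometryError(
            f"wall vertices {verts.tolist()} outside the {ny}x{nx} (y, x) grid"
        )
    rows, cols = [], []
    for (x0, y0), (x1, y1) in zip(verts[:-1], verts[1:]):
        rr, cc = draw_line(y0, x0, y1, x1)
        rows.append(rr)
        cols.append(cc)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    flat = np.unique(rows.astype(np.int64) * nx + cols.astype(np.int64))
    return flat // nx, flat % nx


def apply_walls(volume: np.ndarray, walls: Sequence[Wall]) -> np.ndarray:
    """Zero the walls' rasterized in-plane pixels through all z sections.

    Returns a copy; the input volume is never modified.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise AlignmentError(f"expected a (z, y, x) volume, got {volume.ndim} axes")
    out = volume.copy()
    for wall in walls:
        rows, cols = rasterize_wall(wall, volume.shape[1:])
        out[:, rows, cols] = 0
    return out


def segment_frame(volume: np.ndarray, threshold: float,
                  seed_voxel: tuple[int, int, int],
                  walls: Sequence[Wall] = ()) -> np.ndarray:
    """6-connected component of ``{intensity >= threshold}`` holding the seed.

    ``seed_voxel`` is a (z, y, x) index.  Raises :class:`SeedError` when the
    seed's (wall-zeroed) intensity falls below the threshold.
    """
    volume = np.asarray(volume)
    if threshold <= 0 and np.all(volume > 0):
        warnings.warn(
            "threshold <= 0 on an all-positive volume: the whole frame will "
            "be one component", stacklevel=2)
    walled = apply_walls(volume, walls)
    sz, sy, sx = (int(c) for c in seed_voxel)
    if not (0 <= sz < volume.shape[0] and 0 <= sy < volume.shape[1]
            and 0 <= sx < volume.shape[2]):
        raise SeedError(f"seed voxel {seed_voxel} outside volume {volume.shape}")
    if walled[sz, sy, sx] < threshold:
        raise SeedError(
            f"seed voxel {seed_voxel} intensity {walled[sz, sy, sx]:.3g} "
            f"below threshold {threshold:.3g}"
        )
    labels, _ = ndimage.label(walled >= threshold, structure=CONNECTIVITY_6)
    return labels == labels[sz, sy, sx]


def mask_centroid(volume: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Intensity-weighted centroid of ``volume`` over ``mask``, as a voxel index."""
    weights = np.where(mask, volume, 0.0)
    total = weights.sum()
    if total <= 0:
        raise SeedError("cannot take the centroid of an empty or zero-weight mask")
    com = ndimage.center_of_mass(weights)
    return tuple(int(round(c)) for c in com)


def segment_sequence(stack: ImageStack4D, channel: int | str, threshold: float,
                     seeds_per_frame: Sequence[tuple[int, int, int] | None] | None = None,
                     walls: Sequence[Wall] = ()) -> SegmentationMask:
    """Segment every frame of one channel with a single per-cell threshold.

    A missing per-frame seed is propagated from the previous frame's
    intensity-weighted mask centroid.  A frame whose seed falls below the
    threshold is flagged (empty mask) and processing continues; the next
    frame reuses the last usable seed.
    """
    ci = stack.channel_index(channel)
    n_t = stack.n_frames
    if seeds_per_frame is None:
        seeds_per_frame = [None] * n_t
    if len(seeds_per_frame) != n_t:
        raise AlignmentError(
            f"{len(seeds_per_frame)} seeds for {n_t} frames"
        )
    if seeds_per_frame[0] is None:
        raise SeedError("a seed voxel is required for frame 0")

    masks = np.zeros((n_t,) + stack.shape_zyx, dtype=bool)
    flagged = np.zeros(n_t, dtype=bool)
    used_seeds: list[tuple[int, int, int] | None] = []
    carry = tuple(int(c) for c in seeds_per_frame[0])
    for ti in range(n_t):
        frame_walls = [w for w in walls if w.applies_to(ti)]
        seed = seeds_per_frame[ti]
        seed = tuple(int(c) for c in seed) if seed is not None else carry
        volume = stack.data[ti, ci]
        try:
            masks[ti] = segment_frame(volume, threshold, seed, frame_walls)
            used_seeds.append(seed)
            carry = mask_centroid(volume, masks[ti])
            # the centroid of an elongated cell can fall below threshold
            # (e.g. between soma and process); snap to the seed if needed
            if apply_walls(volume, frame_walls)[carry] < threshold:
                carry = seed
        except SeedError:
            flagged[ti] = True
            used_seeds.append(None)
    return SegmentationMask(masks, float(threshold), used_seeds, flagged, list(walls))


def suggest_threshold(volume: np.ndarray) -> float:
    """Otsu threshold of a volume: an initializer only, never auto-applied."""
    return float(threshold_otsu(np.asarray(volume)))
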