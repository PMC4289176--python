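"""Local marker concentration around a tracked object.

For each time point a cylindrical region (a disk of the requested radius
in x-y, extruded through every z section) is centred on the object's
position; the region is intersected with the segmented cell and the mean
marker intensity inside it is compared with the whole-cell mean
(baseline).  Radii of 1, 2 and 4 um probe the concentration at different
scales around the object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, GeometryError, InvalidConfigError
from .io import ImageStack4D, Track, voxel_centers_um
from .segmentation import SegmentationMask

DEFAULT_RADII_UM = (1.0, 2.0, 4.0)


class LocalMean(NamedTuple):
    mean: float          # NaN when the region is empty
    voxel_count: int
    empty: bool


@dataclass
class ConcentrationProfile:
    """Per-frame local means around a track, one column set per radius."""

    radii_um: tuple[float, ...]
    table: pd.DataFrame  # frame, time_s, radius_um|'baseline', mean_intensity, voxel_count, flag

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _as_masks(mask) -> np.ndarray:
    return mask.masks if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)


def local_mean(stack: ImageStack4D, channel: int | str, mask_frame: np.ndarray,
               frame: int, point_um, radius_um: float) -> LocalMean:
    """Mean intensity of the masked voxels within the cylinder at one frame.

    ``point_um`` is (x, y, z); only its x-y components matter since the
    cylinder spans all z.  An empty intersection is reported with an
    explicit flag, never as a silent zero.
    """
    if radius_um <= 0:
        raise InvalidConfigError(f"radius must be > 0, got {radius_um}")
    ci = stack.channel_index(channel)
    volume = stack.data[frame, ci]
    mask_frame = np.asarray(mask_frame, dtype=bool)
    if mask_frame.shape != volume.shape:
        raise AlignmentError(
            f"mask frame shape {mask_frame.shape} vs volume {volume.shape}")
    px, py = float(point_um[0]), float(point_um[1])
    ex, ey, _ = ((s - 1) * v for s, v in zip(stack.shape_zyx[::-1], stack.voxel_size_um))
    if not (0 <= px <= ex and 0 <= py <= ey):
        raise GeometryError(f"point ({px:.2f}, {py:.2f}) um outside the grid")
    Z, Y, X = voxel_centers_um(stack.shape_zyx, stack.voxel_size_um)
    disk = (X - px) ** 2 + (Y - py) ** 2 <= radius_um ** 2
    region = mask_frame & disk
    count = int(region.sum())
    if count == 0:
        return LocalMean(float("nan"), 0, True)
    return LocalMean(float(volume[region].mean()), count, False)


def concentration_profile(stack: ImageStack4D, channel: int | str,
                          mask: SegmentationMask | np.ndarray, track: Track,
                          radii_um: Sequence[float] = DEFAULT_RADII_UM
                          ) -> ConcentrationProfile:
    """Local means at every radius plus the whole-cell baseline, per frame.

    Frames absent from the track are skipped.  The baseline is the exact
    mean of the marker over the segmented cell.
    """
    radii = tuple(float(r) for r in radii_um)
    if any(b <= a for a, b in zip(radii, radii[1:])) or not radii:
        raise InvalidConfigError(f"radii must be strictly increasing, got {radii}")
    masks = _as_masks(mask)
    ci = stack.channel_index(channel)
    if int(track.frames.max(initial=-1)) >= stack.n_frames:
        raise AlignmentError("track frames extend past the stack")
    rows = []
    for frame, point in zip(track.frames, track.positions_um):
        frame = int(frame)
        t_s = frame * stack.frame_interval_s
        cell = masks[frame]
        n_cell = int(cell.sum())
        baseline = float(stack.data[frame, ci][cell].mean()) if n_cell else float("nan")
        rows.append((frame, t_s, "baseline", baseline, n_cell, n_cell == 0))
        for r in radii:
            lm = local_mean(stack, ci, cell, frame, point, r)
            rows.append((frame, t_s, r, lm.mean, lm.voxel_count, lm.empty))
    table = pd.DataFrame(
        rows, columns=["frame", "time_s", "radius_um", "mean_intensity",
                       "voxel_count", "flag"])
    return ConcentrationProfile(radii, table)
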