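"""Adaptive volumetric kymographs.

The kymograph accumulates the masked fluorescence of a cell in
cross-sections taken one x-y pixel apart along a fixed migration axis.
The axis is the unit vector from the soma centroid to the tip of the
leading process in the first frame; each masked voxel's centre is
projected onto it and assigned to the half-open bin
``[i * delta, (i + 1) * delta)`` with ``delta`` equal to the x-y pixel
size.  Each column of the matrix is either the sum or the max of the
intensities in its cross-section, so with the sum statistic a column
total equals the frame's total masked fluorescence exactly.

Overlays locate the soma (projected min / centre / max) and any tracked
organelle along the same axis, for plotting on top of the matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .exceptions import AlignmentError, DegenerateAxisError, InvalidConfigError
from .io import ImageStack4D, Track, voxel_centers_um
from .segmentation import CONNECTIVITY_6, SegmentationMask


@dataclass
class MigrationAxis:
    """Fixed lab-frame axis: origin at the frame-0 soma centroid (um, xyz)."""

    origin_um: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin_um = np.asarray(self.origin_um, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if norm == 0:
            raise DegenerateAxisError("axis direction has zero length")
        self.direction = self.direction / norm

    def project(self, points_um: np.ndarray) -> np.ndarray:
        """Projected coordinate s = (p - origin) . direction, um."""
        points_um = np.asarray(points_um, dtype=float)
        return (points_um - self.origin_um) @ self.direction


@dataclass
class VolumetricKymograph:
    matrix: np.ndarray          # (bins, frames)
    bin_width_um: float
    bin0_offset_um: float       # physical s of the lower edge of bin 0
    statistic: str              # 'sum' | 'max'
    empty: np.ndarray           # (bins, frames) bool: no voxel fell in the bin
    overlays: pd.DataFrame | None = field(default=None)

    def bin_centers_um(self) -> np.ndarray:
        n = self.matrix.shape[0]
        return self.bin0_offset_um + (np.arange(n) + 0.5) * self.bin_width_um

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix,
                          columns=[f"t{ti}" for ti in range(self.matrix.shape[1])])
        df.insert(0, "s_um", self.bin_centers_um())
        return df


def migration_axis(mask_frame0: np.ndarray, voxel_size_um,
                   soma_centroid_um=None, tip_um=None) -> MigrationAxis:
    """Axis from the soma centroid toward the leading-process tip at frame 0.

    The centroid defaults to the mask's voxel-count centroid; the tip
    defaults to the mask voxel farthest (physically) from the centroid.
    """
    mask_frame0 = np.asarray(mask_frame0, dtype=bool)
    if soma_centroid_um is None or tip_um is None:
        if not mask_frame0.any():
            raise DegenerateAxisError("empty frame-0 mask and no explicit axis points")
        Z, Y, X = voxel_centers_um(mask_frame0.shape, voxel_size_um)
        zz, yy, xx = np.nonzero(mask_frame0)
        pts = np.stack([X[0, 0, xx], Y[0, yy, 0], Z[zz, 0, 0]], axis=1)
        if soma_centroid_um is None:
            soma_centroid_um = pts.mean(axis=0)
        if tip_um is None:
            d2 = ((pts - np.asarray(soma_centroid_um)) ** 2).sum(axis=1)
            tip_um = pts[int(np.argmax(d2))]
    soma_centroid_um = np.asarray(soma_centroid_um, dtype=float)
    tip_um = np.asarray(tip_um, dtype=float)
    delta = tip_um - soma_centroid_um
    if np.linalg.norm(delta) == 0:
        raise DegenerateAxisError("tip point coincides with the soma centroid")
    return MigrationAxis(soma_centroid_um, delta)


def _projected_s(stack: ImageStack4D, axis: MigrationAxis):
    """Projected coordinate s of every voxel centre, shape (z, y, x)."""
    Z, Y, X = voxel_centers_um(stack.shape_zyx, stack.voxel_size_um)
    ox, oy, oz = axis.origin_um
    dx, dy, dz = axis.direction
    return (X - ox) * dx + (Y - oy) * dy + (Z - oz) * dz


def volumetric_kymograph(stack: ImageStack4D, channel: int | str,
                         mask: SegmentationMask | np.ndarray,
                         axis: MigrationAxis,
                         statistic: str = "sum") -> VolumetricKymograph:
    """Bin masked voxel intensities along the axis, one x-y pixel apart.

    Integer input intensities are accumulated in int64, so sum-statistic
    conservation is exact.
    """
    if statistic not in ("sum", "max"):
        raise InvalidConfigError(f"statistic must be 'sum' or 'max', got {statistic!r}")
    masks = mask.masks if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)
    ci = stack.channel_index(channel)
    if masks.shape != (stack.n_frames,) + stack.shape_zyx:
        raise AlignmentError(
            f"mask shape {masks.shape} does not match stack frames {stack.n_frames} "
            f"x volume {stack.shape_zyx}"
        )
    if abs(stack.voxel_size_um[0] - stack.voxel_size_um[1]) > 1e-9:
        raise InvalidConfigError("x and y voxel sizes must match (one x-y pixel bins)")
    delta = stack.voxel_size_um[0]
    s = _projected_s(stack, axis)
    bins = np.floor(s / delta).astype(np.int64)

    # global bin range over all frames so columns share one s axis
    any_mask = masks.any(axis=0)
    if not any_mask.any():
        raise AlignmentError("mask is empty in every frame")
    b0 = int(bins[any_mask].min())
    nbins = int(bins[any_mask].max()) - b0 + 1

    integer_input = np.issubdtype(stack.data.dtype, np.integer)
    acc_dtype = np.int64 if integer_input and statistic == "sum" else np.float64
    matrix = np.zeros((nbins, stack.n_frames), dtype=acc_dtype)
    empty = np.ones((nbins, stack.n_frames), dtype=bool)
    for ti in range(stack.n_frames):
        sel = masks[ti]
        idx = bins[sel] - b0
        vals = stack.data[ti, ci][sel].astype(acc_dtype)
        if statistic == "sum":
            np.add.at(matrix[:, ti], idx, vals)
        else:
            np.maximum.at(matrix[:, ti], idx, vals)
        empty[np.unique(idx), ti] = False
    return VolumetricKymograph(matrix, float(delta), float(b0 * delta),
                               statistic, empty)


def soma_overlay(stack: ImageStack4D, nucleus_channel: int | str,
                 mask: SegmentationMask | np.ndarray, axis: MigrationAxis,
                 margin_um: float = 1.0, threshold: float | None = None,
                 mode: str = "nucleus") -> pd.DataFrame:
    """Per-frame projected soma interval and centre.

    ``mode='nucleus'`` (primary): the soma is the largest 6-connected
    component of the thresholded nucleus channel inside the mask
    (threshold defaults to per-frame Otsu of the in-mask intensities),
    dilated along the axis by ``margin_um``; s_center is the
    intensity-weighted projected centroid.  ``mode='width'`` is a
    nucleus-free fallback: the soma spans the contiguous bins around the
    widest cross-section whose area is >= 50% of the frame maximum.

    Frames without usable signal are flagged and their overlay left NaN.
    """
    masks = mask.masks if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)
    s = _projected_s(stack, axis)
    n_t = stack.n_frames
    out = {"frame": np.arange(n_t), "s_min": np.full(n_t, np.nan),
           "s_center": np.full(n_t, np.nan), "s_max": np.full(n_t, np.nan),
           "flagged": np.zeros(n_t, dtype=bool)}

    if mode == "nucleus":
        ci = stack.channel_index(nucleus_channel)
        for ti in range(n_t):
            vol = stack.data[ti, ci]
            inmask = masks[ti]
            vals = vol[inmask]
            if vals.size == 0 or vals.max() <= 0:
                out["flagged"][ti] = True
                continue
            thr = threshold
            if thr is None:
                uniq = np.unique(vals)
                thr = float(threshold_otsu(vals)) if uniq.size > 1 else float(uniq[0])
            region = inmask & (vol >= thr)
            if not region.any():
                out["flagged"][ti] = True
                continue
            labels, n = ndimage.label(region, structure=CONNECTIVITY_6)
            counts = np.bincount(labels.ravel())[1:]
            region = labels == (1 + int(np.argmax(counts)))
            sv = s[region]
            w = vol[region]
            out["s_min"][ti] = sv.min() - margin_um
            out["s_max"][ti] = sv.max() + margin_um
            out["s_center"][ti] = float((sv * w).sum() / w.sum())
    elif mode == "width":
        delta = stack.voxel_size_um[0]
        bins = np.floor(s / delta).astype(np.int64)
        for ti in range(n_t):
            sel = masks[ti]
            if not sel.any():
                out["flagged"][ti] = True
                continue
            idx = bins[sel]
            b0 = idx.min()
            counts = np.bincount(idx - b0)
            peak = int(np.argmax(counts))
            ok = counts >= 0.5 * counts[peak]
            lo = peak
            while lo > 0 and ok[lo - 1]:
                lo -= 1
            hi = peak
            while hi < len(ok) - 1 and ok[hi + 1]:
                hi += 1
            run = np.arange(lo, hi + 1)
            centers = (b0 + run + 0.5) * delta
            out["s_min"][ti] = (b0 + lo) * delta - margin_um
            out["s_max"][ti] = (b0 + hi + 1) * delta + margin_um
            out["s_center"][ti] = float((centers * counts[run]).sum() / counts[run].sum())
    else:
        raise InvalidConfigError(f"mode must be 'nucleus' or 'width', got {mode!r}")
    return pd.DataFrame(out)


def project_track(track: Track, axis: MigrationAxis) -> pd.Series:
    """Projected coordinate s per present frame (um), indexed by frame."""
    return pd.Series(axis.project(track.positions_um), index=track.frames,
                     name=f"s_{track.track_id}")


def attach_overlays(kym: VolumetricKymograph, soma: pd.DataFrame,
                    organelle_s: pd.Series | None = None) -> VolumetricKymograph:
    """Merge soma and organelle overlays into the kymograph's overlay table."""
    overlays = soma.copy()
    if organelle_s is not None:
        overlays = overlays.merge(
            organelle_s.rename("s_organelle"), how="left",
            left_on="frame", right_index=True)
    else:
        overlays["s_organelle"] = np.nan
    kym.overlays = overlays
    return kym
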