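"""Containers and on-disk formats.

The canonical in-memory image container is :class:`ImageStack4D`, a
five-axis voxel grid ordered ``(t, c, z, y, x)`` with physical voxel sizes
in micrometres and a frame interval in seconds.  All physical coordinates
in the public API are ``(x, y, z)`` triples in micrometres, 0-based,
voxel-centre convention: the centre of voxel ``(z, y, x)`` sits at
``(x * dx, y * dy, z * dz)``.

Formats:

* images       -- multi-page TIFF with an ``axes`` tag plus a JSON metadata
                  sidecar (``<path>.meta.json``) carrying voxel sizes, the
                  frame interval and channel labels;
* tracks       -- CSV with columns ``track_id, frame, channel, x_um, y_um, z_um``;
* walls        -- JSON polylines in x-y pixel coordinates;
* config       -- YAML mapping.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .exceptions import DimensionError, FormatError, MetadataError

logger = logging.getLogger("neurokym")

CANONICAL_AXES = "TCZYX"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack4D:
    """Multi-channel 3D time series.

    Parameters
    ----------
    data
        Voxel intensities, shape ``(t, c, z, y, x)``, non-negative.
    voxel_size_um
        Physical voxel edge lengths ``(x, y, z)`` in micrometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel_labels
        One label per channel; defaulted to ``ch0..chN``.
    """

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    frame_interval_s: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise DimensionError(
                f"expected 5 axes (t, c, z, y, x), got {self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise DimensionError(f"all extents must be >= 1, got {self.data.shape}")
        self.voxel_size_um = tuple(float(v) for v in self.voxel_size_um)
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise MetadataError(f"voxel sizes must be three positive values, got {self.voxel_size_um}")
        self.frame_interval_s = float(self.frame_interval_s)
        if self.frame_interval_s <= 0:
            raise MetadataError(f"frame interval must be > 0, got {self.frame_interval_s}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_labels) != self.data.shape[1]:
            raise MetadataError(
                f"{len(self.channel_labels)} channel labels for {self.data.shape[1]} channels"
            )

    # -- geometry helpers ---------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    @property
    def spacing_zyx(self) -> np.ndarray:
        """Voxel sizes reordered to match array axes (z, y, x)."""
        dx, dy, dz = self.voxel_size_um
        return np.array([dz, dy, dx])

    def axis_coords_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of voxel centres along (z, y, x), in um."""
        nz, ny, nx = self.shape_zyx
        dz, dy, dx = self.spacing_zyx
        return np.arange(nz) * dz, np.arange(ny) * dy, np.arange(nx) * dx

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            try:
                return self.channel_labels.index(channel)
            except ValueError:
                raise MetadataError(
                    f"unknown channel {channel!r}; have {self.channel_labels}"
                ) from None
        return int(channel)

    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


def voxel_centers_um(shape_zyx, voxel_size_um):
    """Broadcastable voxel-centre coordinate grids (Z, Y, X) in um.

    ``voxel_size_um`` is (x, y, z) as everywhere in the public API.
    """
    nz, ny, nx = shape_zyx
    dx, dy, dz = voxel_size_um
    Z = (np.arange(nz) * dz)[:, None, None]
    Y = (np.arange(ny) * dy)[None, :, None]
    X = (np.arange(nx) * dx)[None, None, :]
    return Z, Y, X


@dataclass
class Wall:
    """Exclusion polyline in x-y pixel coordinates, extruded through all z.

    ``frames`` is an optional half-open ``(start, stop)`` frame range the
    wall applies to; ``None`` means every frame.
    """

    vertices: np.ndarray  # (n, 2) float, (x, y) pixel coordinates
    frames: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise FormatError(f"wall vertices must be (n, 2), got {self.vertices.shape}")
        if self.vertices.shape[0] < 2:
            raise FormatError(
                f"a wall needs at least 2 vertices, got {self.vertices.shape[0]}"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise FormatError("wall vertices must be finite")

    def applies_to(self, frame: int) -> bool:
        return self.frames is None or (self.frames[0] <= frame < self.frames[1])


@dataclass
class Track:
    """Time-indexed 3D physical positions of one labelled object.

    Frames are strictly increasing but may have gaps; a frame is "present"
    iff it appears in ``frames``.  Positions are (x, y, z) in micrometres.
    """

    track_id: str
    channel: str
    frames: np.ndarray  # (n,) int, strictly increasing
    positions_um: np.ndarray  # (n, 3) float, (x, y, z)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.ndim != 1 or self.positions_um.shape != (len(self.frames), 3):
            raise FormatError(
                f"track {self.track_id}: frames {self.frames.shape} vs "
                f"positions {self.positions_um.shape}"
            )
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise FormatError(f"track {self.track_id}: frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions_um)):
            raise FormatError(f"track {self.track_id}: non-finite position")

    def __len__(self) -> int:
        return len(self.frames)

    def presence(self, n_frames: int | None = None) -> np.ndarray:
        """Boolean presence flag per frame index 0..n_frames-1."""
        if n_frames is None:
            n_frames = int(self.frames.max()) + 1 if len(self.frames) else 0
        flags = np.zeros(n_frames, dtype=bool)
        flags[self.frames[self.frames < n_frames]] = True
        return flags

    def consecutive_runs(self) -> list[int]:
        """Lengths of maximal runs of consecutive present frames."""
        if len(self.frames) == 0:
            return []
        breaks = np.flatnonzero(np.diff(self.frames) != 1)
        edges = np.concatenate([[-1], breaks, [len(self.frames) - 1]])
        return list(np.diff(edges))

    def subset(self, keep: np.ndarray) -> "Track":
        return Track(self.track_id, self.channel, self.frames[keep], self.positions_um[keep])


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def write_stack(stack: ImageStack4D, path) -> None:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, metadata={"axes": CANONICAL_AXES})
    meta = {
        "axes": CANONICAL_AXES,
        "voxel_size_um": list(stack.voxel_size_um),
        "frame_interval_s": stack.frame_interval_s,
        "channel_labels": list(stack.channel_labels),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_stack(path, axes: str | None = None,
               voxel_size_um=None, frame_interval_s=None,
               channel_labels=None) -> ImageStack4D:
    """Read a TIFF stack and canonicalize its axes to (t, c, z, y, x).

    Axis order is taken from the TIFF series metadata unless ``axes`` is
    given explicitly.  Missing T/C/Z axes of the *declared* order are
    inserted with extent 1; unresolvable axes raise :class:`DimensionError`.
    Voxel sizes, frame interval and channel labels come from the metadata
    sidecar when present and may be overridden by the keyword arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        found = series.axes.upper()
    if axes is not None:
        axes = axes.upper()
        if len(axes) != data.ndim:
            raise DimensionError(
                f"--axes {axes!r} has {len(axes)} letters for {data.ndim} array axes"
            )
    else:
        axes = found
    if (len(set(axes)) != len(axes) or not set(axes) <= set(CANONICAL_AXES)
            or len(axes) != data.ndim):
        raise DimensionError(
            f"cannot resolve axes {found!r} (shape {data.shape}) to (t, c, z, y, x); "
            "pass an explicit axes string"
        )
    # insert missing axes with extent 1, then transpose to canonical order
    for ax in CANONICAL_AXES:
        if ax not in axes:
            data = data[None]
            axes = ax + axes
    data = np.transpose(data, [axes.index(ax) for ax in CANONICAL_AXES])

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    voxel_size_um = voxel_size_um or meta.get("voxel_size_um")
    frame_interval_s = frame_interval_s or meta.get("frame_interval_s")
    channel_labels = channel_labels or meta.get("channel_labels")
    if voxel_size_um is None or frame_interval_s is None:
        raise MetadataError(
            f"no metadata sidecar at {sidecar} and no explicit voxel size / frame interval"
        )
    return ImageStack4D(data, tuple(voxel_size_um), frame_interval_s,
                        list(channel_labels or []))


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ["track_id", "frame", "channel", "x_um", "y_um", "z_um"]


def read_tracks(path) -> list[Track]:
    """Read a track table (CSV); gaps are preserved, duplicates rejected."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("track file %s is empty", path)
        return []
    if df.empty:
        logger.warning("track file %s has no rows", path)
        return []
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()] + 2  # 1-based incl. header
        if len(bad):
            raise FormatError(f"{path}: non-numeric {col} at rows {list(bad)}")
        df[col] = coerced
    df["frame"] = pd.to_numeric(df["frame"], errors="raise", downcast="integer")
    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        rows = list(df.index[dup] + 2)
        raise FormatError(f"{path}: duplicate (track_id, frame) rows at {rows}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        channels = grp["channel"].unique()
        if len(channels) != 1:
            raise FormatError(f"{path}: track {tid} spans channels {list(channels)}")
        tracks.append(Track(
            track_id=str(tid),
            channel=str(channels[0]),
            frames=grp["frame"].to_numpy(),
            positions_um=grp[["x_um", "y_um", "z_um"]].to_numpy(),
        ))
    return tracks


def write_tracks(tracks: Sequence[Track], path) -> None:
    rows = []
    for tr in tracks:
        for f, p in zip(tr.frames, tr.positions_um):
            rows.append((tr.track_id, int(f), tr.channel, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# walls
# ---------------------------------------------------------------------------

def read_walls(path) -> list[Wall]:
    """Read wall polylines from JSON: ``{"walls": [{"vertices": [[x, y], ...], "frames": [a, b]|null}]}``."""
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        logger.warning("wall file %s is empty", path)
        return []
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    entries = doc["walls"] if isinstance(doc, dict) else doc
    walls = []
    for i, entry in enumerate(entries):
        frames = entry.get("frames")
        walls.append(Wall(np.asarray(entry["vertices"], dtype=float),
                          tuple(frames) if frames is not None else None))
    return walls


def write_walls(walls: Sequence[Wall], path) -> None:
    doc = {"walls": [
        {"vertices": w.vertices.tolist(),
         "frames": list(w.frames) if w.frames is not None else None}
        for w in walls
    ]}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# config + misc
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML configuration mapping (empty file -> empty dict)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        return {}
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: config must be a mapping, got {type(doc).__name__}")
    return doc


def dump_json(obj, path) -> None:
    """Deterministic JSON writer used for ground truth and fit reports."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=default) + "\n")
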