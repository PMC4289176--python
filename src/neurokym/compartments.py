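"""Leading-process / soma / trailing-process signal fractions.

Each frame's segmented cell is partitioned along the migration axis by
the soma's projected interval ``[s_min, s_max]`` (from the kymograph soma
overlay): voxels with ``s > s_max`` belong to the leading process,
``s < s_min`` to the trailing process, and the closed interval to the
soma.  The reported fractions are intensity-weighted, i.e. the fraction
of the channel's masked fluorescence in each compartment, and sum to 1
whenever the frame carries signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AlignmentError
from .io import ImageStack4D
from .kymograph import MigrationAxis, _projected_s
from .segmentation import SegmentationMask


@dataclass
class CompartmentFractions:
    table: pd.DataFrame  # frame, time_s, f_leading, f_soma, f_trailing, s_min, s_max, flag

    def fractions(self) -> np.ndarray:
        return self.table[["f_leading", "f_soma", "f_trailing"]].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compartment_fractions(stack: ImageStack4D, channel: int | str,
                          mask: SegmentationMask | np.ndarray,
                          axis: MigrationAxis,
                          soma_interval_per_frame) -> CompartmentFractions:
    """Fraction of masked channel fluorescence per compartment, per frame.

    ``soma_interval_per_frame`` is an ``(n_frames, 2)`` array of projected
    ``(s_min, s_max)`` or a soma-overlay table with those columns; NaN
    intervals and zero-signal frames are flagged with NaN fractions
    rather than silently reported as zero.
    """
    masks = mask.masks if isinstance(mask, SegmentationMask) else np.asarray(mask, dtype=bool)
    ci = stack.channel_index(channel)
    if isinstance(soma_interval_per_frame, pd.DataFrame):
        intervals = soma_interval_per_frame[["s_min", "s_max"]].to_numpy(dtype=float)
    else:
        intervals = np.asarray(soma_interval_per_frame, dtype=float)
    if intervals.shape != (stack.n_frames, 2):
        raise AlignmentError(
            f"soma intervals shape {intervals.shape}, expected ({stack.n_frames}, 2)")
    if masks.shape != (stack.n_frames,) + stack.shape_zyx:
        raise AlignmentError("mask does not align with the stack")

    s = _projected_s(stack, axis)
    rows = []
    for ti in range(stack.n_frames):
        lo, hi = intervals[ti]
        sel = masks[ti]
        vals = stack.data[ti, ci][sel]
        total = float(vals.sum())
        if not np.isfinite(lo) or not np.isfinite(hi) or total <= 0 or not sel.any():
            rows.append((ti, ti * stack.frame_interval_s,
                         np.nan, np.nan, np.nan, lo, hi, True))
            continue
        sv = s[sel]
        lead = float(vals[sv > hi].sum()) / total
        soma = float(vals[(sv >= lo) & (sv <= hi)].sum()) / total
        trail = float(vals[sv < lo].sum()) / total
        rows.append((ti, ti * stack.frame_interval_s, lead, soma, trail, lo, hi, False))
    table = pd.DataFrame(rows, columns=[
        "frame", "time_s", "f_leading", "f_soma", "f_trailing",
        "s_min", "s_max", "flag"])
    return CompartmentFractions(table)
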