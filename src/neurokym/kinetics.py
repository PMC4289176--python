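"""Organelle and nucleus velocity quantification.

The average velocity of a track is the mean of its per-step speeds
``|dp| / dt`` over consecutive present frames (gaps contribute no step),
the convention of per-frame manual tracking tools.  Inclusion rules
follow the assay design: a track counts only if visible for at least
five consecutive frames, and a neuron is classified as migrating when
its net displacement exceeds two cell-body lengths.  Drug-addition
experiments split each track into pre/post segments around the addition
time with an exclusion window for the frames disturbed by pipetting and
refocusing.  Group comparisons use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, InvalidConfigError
from .io import Track

logger = logging.getLogger("neurokym")

#: defaults of the acute migration assay: drug at 24 min, 26-32 min excluded
DEFAULT_DRUG_TIME_S = 24 * 60.0
DEFAULT_EXCLUDED_WINDOW_S = (26 * 60.0, 32 * 60.0)


@dataclass
class VelocityStats:
    """Group summary of per-track mean velocities (um/sec)."""

    velocities: np.ndarray            # per included track
    track_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=float)

    @property
    def n(self) -> int:
        return len(self.velocities)

    @property
    def mean(self) -> float:
        return float(np.mean(self.velocities)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.velocities, ddof=1)) if self.n > 1 else float("nan")


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    degenerate: bool = False


def step_speeds(track: Track, frame_interval_s: float) -> np.ndarray:
    """Instantaneous speeds over consecutive-frame pairs (um/sec)."""
    if frame_interval_s <= 0:
        raise InvalidConfigError("frame interval must be > 0")
    consecutive = np.diff(track.frames) == 1
    disp = np.linalg.norm(np.diff(track.positions_um, axis=0), axis=1)
    return disp[consecutive] / frame_interval_s


def mean_velocity(track: Track, frame_interval_s: float) -> float:
    """Mean per-step speed of one track (um/sec); gaps contribute no step."""
    speeds = step_speeds(track, frame_interval_s)
    if len(speeds) == 0:
        raise InsufficientDataError(
            f"track {track.track_id}: no pair of consecutive present frames")
    return float(np.mean(speeds))


def valid_track(track: Track, min_consecutive: int = 5) -> bool:
    """True iff some run of >= min_consecutive consecutive frames exists."""
    runs = track.consecutive_runs()
    return bool(runs and max(runs) >= min_consecutive)


def classify_migrating(track: Track, cell_body_length_um: float) -> bool:
    """Migrating iff net first-to-last displacement > 2 cell-body lengths."""
    if cell_body_length_um <= 0:
        raise InvalidConfigError("cell body length must be > 0")
    if len(track) < 2:
        return False
    net = float(np.linalg.norm(track.positions_um[-1] - track.positions_um[0]))
    return net > 2.0 * cell_body_length_um


def split_pre_post(track: Track, frame_interval_s: float,
                   drug_time_s: float = DEFAULT_DRUG_TIME_S,
                   excluded_window_s: tuple[float, float] = DEFAULT_EXCLUDED_WINDOW_S
                   ) -> tuple[Track, Track]:
    """Split a track around drug addition, discarding the excluded window.

    pre: t <= drug time; post: t > window end; everything in between is
    discarded, so pre + discarded + post partition the frames.
    """
    w0, w1 = excluded_window_s
    if w1 < w0:
        raise InvalidConfigError(f"excluded window {excluded_window_s} is reversed")
    if w1 < drug_time_s:
        warnings.warn(
            f"excluded window {excluded_window_s} ends before drug addition "
            f"at {drug_time_s} s", stacklevel=2)
    times = track.frames * frame_interval_s
    if len(times) and drug_time_s >= times[-1]:
        warnings.warn(
            f"drug time {drug_time_s} s is at/after the last frame: post side empty",
            stacklevel=2)
    pre = track.subset(times <= drug_time_s)
    post = track.subset(times > max(w1, drug_time_s))
    return pre, post


def welch_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> TestResult:
    """Two-sided Welch unequal-variance t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"each group needs n >= 2, got {len(a)} and {len(b)}")
    summary = dict(mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)), n_a=len(a),
                   mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)), n_b=len(b))
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TestResult(t=0.0, df=float("nan"), p=1.0, degenerate=True, **summary)
        raise InsufficientDataError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(t=float(res.statistic), df=float(res.df),
                      p=float(res.pvalue), **summary)


def group_velocities(tracks: Sequence[Track], frame_interval_s: float,
                     min_consecutive: int = 5) -> tuple[VelocityStats, pd.DataFrame]:
    """Per-track mean velocities with inclusion bookkeeping.

    Returns the stats over included tracks and a table recording, for
    every input track, whether it was included and why not if excluded.
    """
    rows, vels, ids = [], [], []
    for tr in tracks:
        if not valid_track(tr, min_consecutive):
            rows.append((tr.track_id, np.nan, False,
                         f"< {min_consecutive} consecutive frames"))
            continue
        try:
            v = mean_velocity(tr, frame_interval_s)
        except InsufficientDataError as exc:
            rows.append((tr.track_id, np.nan, False, str(exc)))
            continue
        rows.append((tr.track_id, v, True, ""))
        vels.append(v)
        ids.append(tr.track_id)
    table = pd.DataFrame(rows, columns=["track_id", "mean_velocity_um_s",
                                        "included", "reason"])
    return VelocityStats(np.array(vels), ids), table


def basal_motility_series(tracks_by_block: Mapping[str, Sequence[Track]],
                          frame_interval_s: float = 15.0,
                          min_consecutive: int = 5) -> dict[str, VelocityStats]:
    """One VelocityStats per acquisition block of the basal-motility assay.

    Blocks with no valid track are reported as absent (omitted), never as
    zero-velocity groups.
    """
    out: dict[str, VelocityStats] = {}
    for block, tracks in tracks_by_block.items():
        stats_, _ = group_velocities(tracks, frame_interval_s, min_consecutive)
        if stats_.n == 0:
            logger.warning("basal block %r has no valid track; omitted", block)
            continue
        out[block] = stats_
    return out


def stats_table(comparisons: Mapping[str, TestResult]) -> pd.DataFrame:
    rows = [
        (name, r.mean_a, r.sd_a, r.n_a, r.mean_b, r.sd_b, r.n_b, r.t, r.df, r.p)
        for name, r in comparisons.items()
    ]
    return pd.DataFrame(rows, columns=[
        "comparison", "mean_a", "sd_a", "n_a", "mean_b", "sd_b", "n_b",
        "t", "df", "p"])
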