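"""FRAP recovery fitting: half-life and mobile fraction.

The post-bleach intensity of a bleached region is modelled as a
single-exponential recovery with a fixed bleach floor,

    I(t) = I_post + (I_plateau - I_post) * (1 - exp(-k t)),

where ``I_post`` is pinned to the first post-bleach sample and
``(I_plateau, k)`` are fitted by least squares.  The half-life is
``t_1/2 = ln 2 / k`` and the mobile fraction is
``(I_plateau - I_post) / (I_pre - I_post)``.  This is the minimal
standard model that yields both quantities; diffusion-geometry
corrections are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import InsufficientDataError, InvalidConfigError
from .kinetics import TestResult, welch_t_test

logger = logging.getLogger("neurokym")

MIN_POST_SAMPLES = 6


@dataclass
class FrapFit:
    k_per_s: float
    t_half_s: float
    mobile_fraction: float
    plateau: float
    post_level: float
    pre_level: float
    r_squared: float
    converged: bool
    clipped: bool = False          # mobile fraction was clipped into [0, 1]
    diagnostic: str = ""


def _model(t, plateau, k, post):
    return post + (plateau - post) * (1.0 - np.exp(-k * t))


def _initial_rate(times, intensities, post, plateau_guess):
    """Log-linear estimate of k from the normalized recovery deficit."""
    span = plateau_guess - post
    if span <= 0:
        return 0.1
    deficit = (plateau_guess - intensities) / span
    ok = (deficit > 1e-3) & (times > 0)
    if ok.sum() < 2:
        return 0.1
    slope = np.polyfit(times[ok], np.log(deficit[ok]), 1)[0]
    return float(np.clip(-slope, 1e-4, 50.0))


def fit_recovery(times_s: np.ndarray, intensities: np.ndarray,
                 pre_bleach_level: float) -> FrapFit:
    """Fit one post-bleach trace; times start at 0 (the bleach moment)."""
    times = np.asarray(times_s, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if times.shape != intensities.shape or times.ndim != 1:
        raise InvalidConfigError("times and intensities must be matching 1D arrays")
    if len(times) < MIN_POST_SAMPLES:
        raise InsufficientDataError(
            f"need >= {MIN_POST_SAMPLES} post-bleach samples, got {len(times)}")
    if abs(times[0]) > 1e-9:
        raise InvalidConfigError(f"times must start at 0 (bleach), got {times[0]}")
    post = float(intensities[0])
    if pre_bleach_level <= post:
        raise InvalidConfigError(
            f"pre-bleach level {pre_bleach_level} must exceed the first "
            f"post-bleach sample {post}")

    def failed(msg):
        return FrapFit(float("nan"), float("nan"), float("nan"), float("nan"),
                       post, float(pre_bleach_level), float("nan"),
                       converged=False, diagnostic=msg)

    trend = np.polyfit(times, intensities, 1)[0]
    if trend <= 0:
        return failed("non-increasing trace: no recovery to fit")

    plateau0 = max(float(intensities[-1]), post + 1e-6 * (pre_bleach_level - post))
    k0 = _initial_rate(times, intensities, post, plateau0)
    try:
        popt, _ = curve_fit(
            lambda t, plateau, k: _model(t, plateau, k, post),
            times, intensities, p0=[plateau0, k0],
            bounds=([post, 1e-9], [np.inf, np.inf]), maxfev=10000)
    except RuntimeError as exc:
        return failed(f"least-squares failure: {exc}")
    plateau, k = (float(v) for v in popt)
    if k <= 0 or not np.isfinite(k):
        return failed(f"non-positive recovery rate {k}")

    resid = intensities - _model(times, plateau, k, post)
    ss_tot = float(((intensities - intensities.mean()) ** 2).sum())
    r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    mf = (plateau - post) / (pre_bleach_level - post)
    clipped = not (0.0 <= mf <= 1.0)
    return FrapFit(k, float(np.log(2) / k), float(np.clip(mf, 0.0, 1.0)),
                   plateau, post, float(pre_bleach_level), r2,
                   converged=True, clipped=clipped)


def pre_bleach_level(intensities_pre: Sequence[float]) -> float:
    """Pre-bleach reference: the mean of the pre-bleach samples."""
    arr = np.asarray(intensities_pre, dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("no pre-bleach samples supplied")
    return float(arr.mean())


def fit_trace_table(df: pd.DataFrame) -> FrapFit:
    """Fit a single-trace table with columns time_s, intensity, phase."""
    for col in ("time_s", "intensity", "phase"):
        if col not in df.columns:
            raise InvalidConfigError(f"trace table missing column {col!r}")
    pre = df[df["phase"] == "pre"]["intensity"]
    post = df[df["phase"] == "post"]
    if pre.empty:
        raise InvalidConfigError("trace has no pre-bleach samples")
    t0 = post["time_s"].iloc[0]
    return fit_recovery(post["time_s"].to_numpy() - t0,
                        post["intensity"].to_numpy(),
                        pre_bleach_level(pre))


def summarize_frap(fits_by_condition: Mapping[str, Sequence[FrapFit]],
                   control: str) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Group mean +/- SD half-life over converged fits, plus Welch tests.

    Only converged fits enter the summary; a group with fewer than two
    converged fits is excluded with a warning.  Every non-control group is
    tested against the control group's half-lives.
    """
    groups: dict[str, np.ndarray] = {}
    rows = []
    for cond, fits in fits_by_condition.items():
        th = np.array([f.t_half_s for f in fits if f.converged])
        if len(th) < 2:
            logger.warning("condition %r has %d converged fit(s); excluded",
                           cond, len(th))
            continue
        groups[cond] = th
        rows.append((cond, float(th.mean()), float(th.std(ddof=1)), len(th)))
    summary = pd.DataFrame(rows, columns=["condition", "mean_t_half_s",
                                          "sd_t_half_s", "n"])
    tests: dict[str, TestResult] = {}
    if control in groups:
        for cond, th in groups.items():
            if cond != control:
                tests[f"{cond}_vs_{control}"] = welch_t_test(th, groups[control])
    else:
        logger.warning("control condition %r absent from the summary", control)
    return summary, tests


def fits_table(fits: Mapping[str, Sequence[FrapFit]] | Sequence[tuple[str, str, FrapFit]]
               ) -> pd.DataFrame:
    """Flat per-trace fit table (trace_id, condition, k, t_half, mf, r2, converged)."""
    rows = []
    if isinstance(fits, Mapping):
        items = [(f"{cond}_{i:03d}", cond, f)
                 for cond, fs in fits.items() for i, f in enumerate(fs)]
    else:
        items = list(fits)
    for trace_id, cond, f in items:
        rows.append((trace_id, cond, f.k_per_s, f.t_half_s, f.mobile_fraction,
                     f.r_squared, f.converged))
    return pd.DataFrame(rows, columns=[
        "trace_id", "condition", "k_per_s", "t_half_s", "mobile_fraction",
        "r2", "converged"])
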