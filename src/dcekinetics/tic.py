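"""Time-signal intensity curves (TICs) from triplicate-ROI measurements.

A subject's raw data are a grid of ROI signal intensities: ``n_pre``
pre-contrast repetitions and ``n_post`` post-contrast scans, each
measured in three ROIs (one per imaging plane).  The TIC is the
per-scan mean of the three ROIs plotted against scan completion time;
the baseline S_0 is the mean of all pre-contrast ROI values (2 x 3 = 6
with the default schedule).

Curve shape falls into the standard three kinetic categories:
type I (persistent rise), type II (plateau), type III (washout).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .schedule import ScanSchedule, scan_completion_time

__all__ = ["RoiSignalSeries", "TIC", "TICType", "build_tic", "classify_tic"]


@dataclass(frozen=True)
class RoiSignalSeries:
    """Raw per-scan, per-ROI signal intensities for one subject.

    ``signals`` has shape (n_pre + n_post, n_roi); rows 0..n_pre-1 are
    the pre-contrast repetitions, the rest post-contrast scans 1..n_post
    in time order.  All intensities must be positive and finite — a
    missing replicate is an error, never imputed.
    """

    subject_id: str
    dose: float
    signals: np.ndarray
    n_pre: int = 2

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "signals", sig)
        if sig.ndim != 2:
            raise ValueError("signals must be a 2-D (scan x ROI) array")
        if sig.shape[0] <= self.n_pre:
            raise ValueError("series must contain post-contrast scans")
        if not np.all(np.isfinite(sig)):
            bad = np.argwhere(~np.isfinite(sig))[0]
            raise ValueError(
                f"subject {self.subject_id}: missing/non-finite replicate at "
                f"scan row {bad[0]}, ROI {bad[1]} (no imputation)"
            )
        if np.any(sig <= 0):
            raise ValueError(
                f"subject {self.subject_id}: signal intensities must be positive"
            )

    @property
    def n_post(self) -> int:
        return self.signals.shape[0] - self.n_pre

    @property
    def n_roi(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class TIC:
    """One subject's time-signal intensity curve.

    ``s0`` is the pre-contrast baseline; ``s`` holds the post-contrast
    means S_1..S_n in scan order; ``times`` the matching completion
    times T_1..T_n (seconds since injection start).
    """

    s0: float
    s: np.ndarray
    times: np.ndarray
    subject_id: str = ""
    dose: float = float("nan")

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "times", t)
        if self.s0 <= 0:
            raise ValueError("baseline s0 must be positive")
        if s.shape != t.shape or s.ndim != 1:
            raise ValueError("s and times must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("completion times must be strictly increasing")

    @property
    def n_post(self) -> int:
        return self.s.size


class TICType(Enum):
    """Kinetic curve category."""

    I_persistent = "I"
    II_plateau = "II"
    III_washout = "III"


def build_tic(series: RoiSignalSeries,
              schedule: ScanSchedule | None = None) -> TIC:
    """Average ROI replicates into a TIC on the schedule's time grid.

    S_0 is the mean of every pre-contrast ROI value; S_n the mean of the
    three ROI values of post-scan n; times are completion times.
    """
    schedule = schedule or ScanSchedule(n_pre=series.n_pre,
                                        n_post=series.n_post)
    if series.n_pre != schedule.n_pre or series.n_post != schedule.n_post:
        raise ValueError(
            f"subject {series.subject_id}: series has {series.n_pre} pre / "
            f"{series.n_post} post scans, schedule expects "
            f"{schedule.n_pre}/{schedule.n_post}"
        )
    s0 = float(series.signals[: series.n_pre].mean())
    s = series.signals[series.n_pre:].mean(axis=1)
    times = np.array(schedule.completion_times)
    return TIC(s0=s0, s=s, times=times,
               subject_id=series.subject_id, dose=series.dose)


def classify_tic(tic: TIC, early_window_s: float = 137.0,
                 tolerance: float = 0.10) -> TICType:
    """Classify a TIC as persistent (I), plateau (II) or washout (III).

    The late signal S_last is compared with the signal S_ref of the
    post-scan completing nearest ``early_window_s``:
    Delta = (S_last - S_ref) / S_ref.  Delta > +tolerance -> type I,
    |Delta| <= tolerance -> type II, Delta < -tolerance -> type III.
    Invariant under rescaling the whole curve by a positive constant.
    """
    idx = int(np.argmin(np.abs(tic.times - early_window_s)))
    s_ref = tic.s[idx]
    delta = (tic.s[-1] - s_ref) / s_ref
    if delta > tolerance:
        return TICType.I_persistent
    if delta < -tolerance:
        return TICType.III_washout
    return TICType.II_plateau
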