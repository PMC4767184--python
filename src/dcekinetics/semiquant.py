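"""Semi-quantitative (model-free) kinetic parameters of a TIC.

Ten descriptors computed directly from the curve, using completion
times throughout:

===========  ====================================================
e_first      (S_1 - S_0) / S_0           initial enhancement
v_first      (S_1 - S_0) / T_1           initial enhancement velocity
s_max        max over S_1..S_last        peak signal
t_peak       completion time of the first scan attaining s_max
e_max        (S_max - S_0) / S_0         peak enhancement
v_max        (S_max - S_0) / T_peak      peak enhancement velocity
e_wash       (S_max - S_last) / S_max    washout fraction
v_wash       (S_max - S_last) / (T_last - T_peak)
ser          (S_1 - S_0) / (S_last - S_0)   signal enhancement ratio
slope_wash   OLS slope of S against scan count after the peak
===========  ====================================================

The washout slope regresses signal on x = 0, 1, 2, ... counting scans
from the peak scan (the peak itself at x = 0), so its units are signal
per scan; ``washout_slope_per_second`` is the seconds-abscissa variant.
Degenerate denominators (peak at the last scan; S_last = S_0) yield
flagged values, never exceptions, so cohort tables keep every row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tic import TIC

__all__ = [
    "SemiQuantParams",
    "WashoutFit",
    "early_params",
    "peak_params",
    "washout_params",
    "washout_slope",
    "washout_slope_per_second",
    "all_params",
]

#: column order used when tabulating parameters cohort-wide
PARAM_COLUMNS = ["s0", "e_first", "v_first", "s_max", "t_peak", "e_max",
                 "v_max", "e_wash", "v_wash", "ser", "slope_wash"]


@dataclass(frozen=True)
class WashoutFit:
    """OLS line through the post-peak signals against scan count."""

    slope: float
    intercept: float
    r: float            # NaN when the fit is degenerate (constant y)
    n_points: int

    @property
    def r_defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class SemiQuantParams:
    """The full per-subject descriptor record.

    ``ser`` is NaN with ``ser_defined`` False when S_last = S_0;
    ``v_wash`` is 0 with ``washout_degenerate`` True when the peak falls
    on the last scan.
    """

    s0: float
    e_first: float
    v_first: float
    s_max: float
    t_peak: float
    e_max: float
    v_max: float
    e_wash: float
    v_wash: float
    ser: float
    slope_wash: float
    r_wash: float
    ser_defined: bool = True
    washout_degenerate: bool = False
    subject_id: str = ""
    dose: float = float("nan")


def early_params(tic: TIC) -> tuple[float, float]:
    """Initial enhancement fraction and velocity: uses S_1 and T_1."""
    e_first = (tic.s[0] - tic.s0) / tic.s0
    v_first = (tic.s[0] - tic.s0) / tic.times[0]
    return float(e_first), float(v_first)


def peak_params(tic: TIC) -> tuple[float, float, float, float]:
    """(s_max, t_peak, e_max, v_max); ties broken by first occurrence."""
    ipk = int(np.argmax(tic.s))
    s_max = float(tic.s[ipk])
    t_peak = float(tic.times[ipk])
    e_max = (s_max - tic.s0) / tic.s0
    v_max = (s_max - tic.s0) / t_peak
    return s_max, t_peak, float(e_max), float(v_max)


def washout_params(tic: TIC) -> tuple[float, float, float, bool, bool]:
    """(e_wash, v_wash, ser, ser_defined, washout_degenerate).

    e_wash = (S_max - S_last)/S_max; v_wash = (S_max - S_last)/(T_last -
    T_peak), reported as 0 with the degenerate flag when the peak is the
    last scan; ser = (S_1 - S_0)/(S_last - S_0), NaN with ser_defined
    False when S_last = S_0.
    """
    s_max, t_peak, _, _ = peak_params(tic)
    s_last = float(tic.s[-1])
    t_last = float(tic.times[-1])
    e_wash = (s_max - s_last) / s_max
    if t_peak == t_last:
        v_wash, degenerate = 0.0, True
    else:
        v_wash, degenerate = (s_max - s_last) / (t_last - t_peak), False
    if s_last == tic.s0:
        ser, ser_defined = float("nan"), False
    else:
        ser, ser_defined = (tic.s[0] - tic.s0) / (s_last - tic.s0), True
    return float(e_wash), float(v_wash), float(ser), ser_defined, degenerate


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Plain least-squares line with Pearson r (NaN when y is constant)."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    syy = float(((y - ym) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else float("nan")
    return slope, intercept, r


def washout_slope(tic: TIC) -> WashoutFit:
    """OLS fit of post-peak signal against scan count from the peak.

    The peak scan anchors the line at x = 0; slope units are signal per
    scan.  For a curve whose post-peak decay is exactly linear the
    intercept equals S_max.  Requires at least 3 points at or after the
    peak.
    """
    ipk = int(np.argmax(tic.s))
    y = tic.s[ipk:]
    if y.size < 3:
        raise ValueError(
            f"washout fit needs >= 3 scans at/after the peak, got {y.size}"
        )
    x = np.arange(y.size, dtype=float)
    slope, intercept, r = _ols_line(x, y)
    return WashoutFit(slope=slope, intercept=intercept, r=r, n_points=y.size)


def washout_slope_per_second(tic: TIC) -> WashoutFit:
    """Variant of :func:`washout_slope` with time (s) as the abscissa.

    Units are signal per second; not the tabulated slope_wash.
    """
    ipk = int(np.argmax(tic.s))
    y = tic.s[ipk:]
    if y.size < 3:
        raise ValueError(
            f"washout fit needs >= 3 scans at/after the peak, got {y.size}"
        )
    x = tic.times[ipk:].astype(float)
    slope, intercept, r = _ols_line(x, y)
    return WashoutFit(slope=slope, intercept=intercept, r=r, n_points=y.size)


def all_params(tic: TIC) -> SemiQuantParams:
    """Compute the full descriptor record in one consistent pass."""
    e_first, v_first = early_params(tic)
    s_max, t_peak, e_max, v_max = peak_params(tic)
    e_wash, v_wash, ser, ser_defined, degenerate = washout_params(tic)
    try:
        fit = washout_slope(tic)
        slope, r_wash = fit.slope, fit.r
    except ValueError:  # peak too close to the last scan for a 3-point fit
        slope, r_wash = float("nan"), float("nan")
    return SemiQuantParams(
        s0=float(tic.s0), e_first=e_first, v_first=v_first,
        s_max=s_max, t_peak=t_peak, e_max=e_max, v_max=v_max,
        e_wash=e_wash, v_wash=v_wash, ser=ser,
        slope_wash=slope, r_wash=r_wash,
        ser_defined=ser_defined, washout_degenerate=degenerate,
        subject_id=tic.subject_id, dose=tic.dose,
    )
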