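"""Sucrose-gradient A254 profile quantification.

A polysome/subunit profile is an absorbance trace (254 nm, percent of full
scale) along the gradient.  In Arabidopsis whole-cell extracts the 40S
small subunit resolves as the first peak while the 60S subunit sediments
together with the 80S monosome as a single composite peak; the statistic of
interest is the area ratio R = area(60S-80S) / area(40S).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import DataError


@dataclass(frozen=True)
class AbsorbanceTrace:
    """Gradient position (strictly increasing) vs A254 (% of full scale)."""

    positions: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if pos.ndim != 1 or pos.shape != ab.shape:
            raise DataError("invalid trace: positions and absorbance must match 1-d")
        if pos.size > 1 and np.any(np.diff(pos) <= 0):
            raise DataError("invalid trace: positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "absorbance", ab)

    def __len__(self) -> int:
        return self.positions.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "a254_percent": self.absorbance}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbsorbanceTrace":
        for col in ("position", "a254_percent"):
            if col not in df.columns:
                raise DataError(f"schema mismatch: {col}")
        return cls(df["position"].to_numpy(), df["a254_percent"].to_numpy())


@dataclass(frozen=True)
class Peak:
    label: str  # "40S", "60S-80S" or "other"
    apex: float  # gradient position of the maximum
    left: float  # left boundary position (flanking minimum)
    right: float  # right boundary position
    area: float  # trapezoidal area between the boundaries

    def __post_init__(self) -> None:
        if not (self.left <= self.apex <= self.right):
            raise DataError("invalid peak: boundaries must bracket the apex")
        if self.area < 0:
            raise DataError("invalid peak: negative area")


@dataclass(frozen=True)
class PeakSet:
    peaks: tuple[Peak, ...]

    def __post_init__(self) -> None:
        for label in ("40S", "60S-80S"):
            if sum(p.label == label for p in self.peaks) > 1:
                raise DataError(f"invalid peak set: duplicate {label} label")

    def get(self, label: str) -> Peak | None:
        for p in self.peaks:
            if p.label == label:
                return p
        return None

    def __len__(self) -> int:
        return len(self.peaks)

    def to_records(self) -> list[dict]:
        return [
            {
                "label": p.label,
                "apex": p.apex,
                "left": p.left,
                "right": p.right,
                "area": p.area,
            }
            for p in self.peaks
        ]


def correct_baseline(
    trace: AbsorbanceTrace,
    window_frac: float = 0.30,
    window: int | None = None,
    smooth: int = 0,
    pedestal: bool = True,
) -> AbsorbanceTrace:
    """Subtract a rolling-minimum baseline.

    The trace is cut into consecutive windows of ``window`` samples; the
    minimum of each window anchors a piecewise-linear baseline (linearly
    extrapolated at the trace ends) which is subtracted.  On a linear drift
    the anchors sit exactly on the drift line, so offsets and slopes are
    removed without touching peaks narrower than the window.  The corrected
    trace is clipped at zero, so it is non-negative by construction.

    Parameters
    ----------
    window_frac : float
        Window width as a fraction of the trace length; must exceed the
        widest peak's footprint for the peak areas to be preserved.
    window : int, optional
        Explicit window width in samples (overrides ``window_frac``).
    smooth : int
        Optional boxcar pre-smoothing width in samples (0 = off); area
        preserving, recommended at roughly the narrowest peak's sigma for
        noisy detector traces.
    pedestal : bool
        Re-centre the background at zero using the median of below-10%%-of-
        maximum samples (noise on the window minima otherwise leaves a small
        positive pedestal that inflates integrated areas).
    """
    n = len(trace)
    if n < 10:
        raise DataError("trace too short: need at least 10 samples")
    w = window if window is not None else max(3, int(round(window_frac * n)))
    w = max(2, min(w, n))
    x, y = trace.positions, trace.absorbance
    if smooth and smooth > 1:
        y = uniform_filter1d(y, size=int(smooth), mode="nearest")
    anchor_idx = [i + int(np.argmin(y[i : i + w])) for i in range(0, n, w)]
    if len(anchor_idx) == 1:
        baseline = np.full(n, y[anchor_idx[0]])
    else:
        ax, ay = x[anchor_idx], y[anchor_idx]
        slope_lo = (ay[1] - ay[0]) / (ax[1] - ax[0])
        slope_hi = (ay[-1] - ay[-2]) / (ax[-1] - ax[-2])
        baseline = np.interp(x, ax, ay)
        left = x < ax[0]
        right = x > ax[-1]
        baseline[left] = ay[0] + slope_lo * (x[left] - ax[0])
        baseline[right] = ay[-1] + slope_hi * (x[right] - ax[-1])
    corrected = y - baseline
    if pedestal and corrected.max() > 0:
        bg = corrected < 0.1 * corrected.max()
        if bg.sum() >= max(10, n // 10):
            corrected = corrected - np.median(corrected[bg])
    corrected = np.maximum(corrected, 0.0)
    return AbsorbanceTrace(trace.positions, corrected)


def _boundaries(y: np.ndarray, apexes: list[int]) -> list[tuple[int, int]]:
    """Valley-to-valley boundaries: the minimum between consecutive apexes
    (or to the trace ends for the outermost peaks)."""
    bounds = []
    for i, a in enumerate(apexes):
        lo = 0 if i == 0 else apexes[i - 1]
        hi = y.size - 1 if i == len(apexes) - 1 else apexes[i + 1]
        left = lo + int(np.argmin(y[lo : a + 1])) if a > lo else lo
        right = a + int(np.argmin(y[a : hi + 1])) if hi > a else hi
        bounds.append((left, right))
    return bounds


def analyze_profile(
    trace: AbsorbanceTrace,
    prominence_frac: float = 0.05,
    merge_valley_frac: float = 0.50,
) -> PeakSet:
    """Detect, integrate and label the subunit peaks of a corrected trace.

    Local maxima with prominence above ``prominence_frac`` of the trace
    maximum are kept; adjacent maxima whose connecting valley stays above
    ``merge_valley_frac`` of the lower apex are merged into one region
    (the 60S shoulder sedimenting with the 80S).  Peak boundaries are the
    flanking minima; the area is the trapezoidal integral above the
    valley-to-valley baseline segment joining the two boundary points (zero
    on a trace whose valleys sit at zero, but robust to residual local
    background).  The two leading peaks, in sedimentation order, are
    labelled 40S and 60S-80S; any further peaks are labelled "other".
    A flat trace yields an empty PeakSet.
    """
    x, y = trace.positions, trace.absorbance
    ymax = y.max() if len(trace) else 0.0
    if len(trace) < 3 or ymax <= 0:
        return PeakSet(())
    if y.min() > 0.05 * ymax:
        warnings.warn(
            "trace does not touch zero; it may not be baseline-corrected",
            UserWarning,
            stacklevel=2,
        )
    apexes, _ = find_peaks(y, prominence=prominence_frac * ymax)
    apexes = list(apexes)
    if not apexes:
        return PeakSet(())

    # merge under-resolved neighbours (valley > merge_valley_frac of lower apex)
    merged: list[list[int]] = [[apexes[0]]]
    for a in apexes[1:]:
        prev = merged[-1][-1]
        valley = y[prev : a + 1].min()
        if valley > merge_valley_frac * min(y[prev], y[a]):
            merged[-1].append(a)
        else:
            merged.append([a])
    group_apex = [max(g, key=lambda i: y[i]) for g in merged]

    bounds = _boundaries(y, group_apex)
    peaks = []
    for rank, (a, (l, r)) in enumerate(zip(group_apex, bounds)):
        label = "40S" if rank == 0 else ("60S-80S" if rank == 1 else "other")
        xs, ys = x[l : r + 1], y[l : r + 1]
        chord = np.interp(xs, [x[l], x[r]], [y[l], y[r]])
        area = float(np.trapezoid(np.maximum(ys - chord, 0.0), xs))
        peaks.append(
            Peak(label=label, apex=float(x[a]), left=float(x[l]), right=float(x[r]),
                 area=max(area, 0.0))
        )
    return PeakSet(tuple(peaks))


def subunit_ratio(peaks: PeakSet) -> float:
    """R = area(60S-80S) / area(40S) for one gradient run."""
    p40, p6080 = peaks.get("40S"), peaks.get("60S-80S")
    if p40 is None or p6080 is None:
        raise DataError("ratio undefined: both 40S and 60S-80S peaks required")
    if p40.area <= 0:
        raise DataError("ratio undefined: zero 40S area")
    return p6080.area / p40.area


def average_ratio(ratios: Sequence[float]) -> float:
    """Arithmetic mean of replicate subunit ratios, reported to 2 decimals."""
    vals = list(ratios)
    if not vals:
        raise DataError("ratio undefined: need at least one replicate ratio")
    return round(float(np.mean(vals)), 2)
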