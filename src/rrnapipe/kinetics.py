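"""First-order processing cascade for the major Arabidopsis pre-rRNA species.

The model tracks the three abundant precursors of the ITS1-first maturation
pathway — the primary 45S transcript, the 35S generated by endonucleolytic
cleavage at the P site in the 5'ETS, and the P-A3 intermediate spanning the
P site to the A3 site in ITS1 — as a linear compartmental cascade with
constant synthesis flux into the 45S pool::

    d[45S]/dt  = sigma        - k45 * [45S]
    d[35S]/dt  = k45 * [45S]  - k35 * [35S]
    d[P-A3]/dt = alpha * k35 * [35S] - kpa3 * [P-A3]

``sigma`` is the RNA-polymerase-I synthesis flux (signal units per hour),
``k45`` the 45S→35S processing rate, ``k35`` the total 35S removal rate of
which a fraction ``alpha`` is converted to P-A3 (the remainder is degraded,
e.g. by 3'-5' exosome trimming), and ``kpa3`` the P-A3
processing/degradation rate.  All rates are first order, in h⁻¹.

Heat stress and recovery are modelled as piecewise-constant parameter
regimes (22°C baseline, 37°C heat, 22°C recovery) stitched together
continuously by :func:`simulate_schedule`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

from .errors import ModelError

#: Species names, in cascade order.
SPECIES = ("45S", "35S", "P-A3")

#: Recognised temperature regimes.
REGIMES = ("baseline22", "heat37", "recovery22")

#: Relative separation below which two rates are treated as numerically equal
#: and the matrix-exponential path is used instead of the explicit
#: three-exponential formula (avoids catastrophic cancellation).
_DEGENERATE_RTOL = 1e-6


@dataclass(frozen=True)
class RateParameters:
    """Per-regime kinetic constants of the cascade model.

    Parameters
    ----------
    sigma : float
        45S synthesis flux, signal units · h⁻¹.
    k45 : float
        First-order 45S → 35S processing rate, h⁻¹.
    k35 : float
        First-order total 35S removal rate, h⁻¹.
    alpha : float
        Fraction of removed 35S converted to P-A3 (dimensionless, in [0, 1]).
    kpa3 : float
        First-order P-A3 processing/degradation rate, h⁻¹.
    """

    sigma: float
    k45: float
    k35: float
    alpha: float
    kpa3: float

    def __post_init__(self) -> None:
        vals = (self.sigma, self.k45, self.k35, self.alpha, self.kpa3)
        if not all(np.isfinite(v) for v in vals):
            raise ModelError("invalid model input: non-finite parameter")
        if any(v < 0 for v in vals):
            raise ModelError("invalid model input: negative parameter")
        if not 0.0 <= self.alpha <= 1.0:
            raise ModelError("invalid model input: alpha outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateParameters":
        return cls(**{k: float(d[k]) for k in ("sigma", "k45", "k35", "alpha", "kpa3")})


@dataclass(frozen=True)
class Segment:
    """One constant-parameter stretch of the temperature schedule."""

    start_h: float
    end_h: float
    regime: str

    def __post_init__(self) -> None:
        if self.end_h <= self.start_h:
            raise ModelError("invalid model input: segment must have end_h > start_h")
        if self.regime not in REGIMES:
            raise ModelError(f"invalid model input: unknown regime {self.regime!r}")


class RegimeSchedule:
    """Ordered, contiguous temperature regimes covering [0, span].

    Segments must be contiguous, non-overlapping and start at t = 0 h.
    """

    def __init__(self, segments: Iterable[Segment]):
        segs = list(segments)
        if not segs:
            raise ModelError("invalid model input: empty schedule")
        if segs[0].start_h != 0.0:
            raise ModelError("invalid model input: schedule must start at t=0")
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start_h != prev.end_h:
                raise ModelError("invalid model input: schedule segments must be contiguous")
        self.segments: tuple[Segment, ...] = tuple(segs)

    @property
    def start_h(self) -> float:
        return self.segments[0].start_h

    @property
    def end_h(self) -> float:
        return self.segments[-1].end_h

    def regime_at(self, t: float) -> str:
        """Regime label at time ``t``; boundary times belong to the earlier segment
        (so a sample taken at the end of the heat phase is labelled heat)."""
        if t < self.start_h or t > self.end_h:
            raise ModelError("time out of schedule range")
        if t == self.start_h:
            return self.segments[0].regime
        for seg in self.segments:
            if seg.start_h < t <= seg.end_h:
                return seg.regime
        raise ModelError("time out of schedule range")  # pragma: no cover

    def to_dicts(self) -> list[dict]:
        return [
            {"start_h": s.start_h, "end_h": s.end_h, "regime": s.regime}
            for s in self.segments
        ]

    @classmethod
    def from_dicts(cls, rows: Iterable[Mapping]) -> "RegimeSchedule":
        return cls(
            Segment(float(r["start_h"]), float(r["end_h"]), str(r["regime"]))
            for r in rows
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, RegimeSchedule) and self.segments == other.segments

    def __repr__(self) -> str:
        inner = ", ".join(f"{s.regime}[{s.start_h}-{s.end_h}h]" for s in self.segments)
        return f"RegimeSchedule({inner})"


def _validate_state(y0: Sequence[float]) -> np.ndarray:
    y = np.asarray(y0, dtype=float)
    if y.shape != (3,):
        raise ModelError("invalid model input: state must have exactly three components")
    if not np.all(np.isfinite(y)):
        raise ModelError("invalid model input: non-finite state")
    if np.any(y < 0):
        raise ModelError("invalid model input: negative state")
    return y


def steady_state(params: RateParameters) -> np.ndarray:
    """22°C equilibrium abundances (45S, 35S, P-A3) = (σ/k45, σ/k35, α·σ/kpa3).

    Raises
    ------
    ModelError
        If any required rate is zero ("no finite steady state").
    """
    if params.k45 <= 0 or params.k35 <= 0 or params.kpa3 <= 0:
        raise ModelError("no finite steady state: all of k45, k35, kpa3 must be > 0")
    return np.array(
        [
            params.sigma / params.k45,
            params.sigma / params.k35,
            params.alpha * params.sigma / params.kpa3,
        ]
    )


def _is_generic(p: RateParameters) -> bool:
    ks = np.array([p.k45, p.k35, p.kpa3])
    if np.any(ks <= 0):
        return False
    scale = max(ks.max(), 1.0)
    seps = (
        abs(p.k45 - p.k35),
        abs(p.k35 - p.kpa3),
        abs(p.k45 - p.kpa3),
    )
    return min(seps) > _DEGENERATE_RTOL * scale


def _solve_generic(p: RateParameters, y0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Explicit three-exponential solution; requires positive, well-separated rates."""
    k1, k2, k3, a, s = p.k45, p.k35, p.kpa3, p.alpha, p.sigma
    a0 = s / k1
    a1 = y0[0] - a0
    b0 = s / k2
    b1 = k1 * a1 / (k2 - k1)
    b2 = y0[1] - b0 - b1
    c0 = a * s / k3
    c1 = a * k2 * b1 / (k3 - k1)
    c2 = a * k2 * b2 / (k3 - k2)
    c3 = y0[2] - c0 - c1 - c2
    e1 = np.exp(-k1 * t)
    e2 = np.exp(-k2 * t)
    e3 = np.exp(-k3 * t)
    out = np.empty((t.size, 3))
    out[:, 0] = a0 + a1 * e1
    out[:, 1] = b0 + b1 * e1 + b2 * e2
    out[:, 2] = c0 + c1 * e1 + c2 * e2 + c3 * e3
    return out


def _solve_expm(p: RateParameters, y0: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Exact solution via the exponential of the affine system's augmented matrix.

    Handles every degeneracy (equal rates, zero rates) without special-casing.
    """
    m = np.array(
        [
            [-p.k45, 0.0, 0.0, p.sigma],
            [p.k45, -p.k35, 0.0, 0.0],
            [0.0, p.alpha * p.k35, -p.kpa3, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    z0 = np.append(y0, 1.0)
    out = np.empty((t.size, 3))
    for i, ti in enumerate(t):
        out[i] = (expm(m * ti) @ z0)[:3]
    return out


def solve_cascade(
    params: RateParameters, y0: Sequence[float], times: Sequence[float]
) -> np.ndarray:
    """Exact trajectory of the cascade from state ``y0`` at t = 0.

    Parameters
    ----------
    params : RateParameters
    y0 : sequence of 3 floats
        Abundances (45S, 35S, P-A3) at t = 0; must be non-negative.
    times : sequence of float
        Non-negative, strictly increasing evaluation times in hours.

    Returns
    -------
    ndarray of shape (len(times), 3)
        Columns ordered as :data:`SPECIES`.
    """
    y = _validate_state(y0)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ModelError("invalid model input: times must be a non-empty 1-d sequence")
    if np.any(t < 0):
        raise ModelError("invalid model input: negative time")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ModelError("invalid model input: times must be strictly increasing")
    if _is_generic(params):
        return _solve_generic(params, y, t)
    return _solve_expm(params, y, t)


def simulate_schedule(
    schedule: RegimeSchedule,
    params_by_regime: Mapping[str, RateParameters],
    y0: Sequence[float],
    times: Sequence[float],
) -> np.ndarray:
    """Piecewise-constant-parameter trajectory over a heat/recovery schedule.

    The state is continuous at segment boundaries; restricted to a single
    segment this reduces to :func:`solve_cascade`.

    Raises
    ------
    ModelError
        If a requested time falls outside the schedule span ("time out of
        schedule range") or a segment's regime has no parameters
        ("unparameterized regime").
    """
    y = _validate_state(y0)
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ModelError("invalid model input: times must be a non-empty 1-d sequence")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ModelError("invalid model input: times must be strictly increasing")
    if np.any(t < schedule.start_h) or np.any(t > schedule.end_h):
        raise ModelError("time out of schedule range")
    for seg in schedule.segments:
        if seg.regime not in params_by_regime:
            raise ModelError(f"unparameterized regime: {seg.regime}")

    out = np.empty((t.size, 3))
    # times exactly at the schedule start are the initial state
    at_start = t == schedule.start_h
    out[at_start] = y
    y_seg = y
    for seg in schedule.segments:
        p = params_by_regime[seg.regime]
        mask = (t > seg.start_h) & (t <= seg.end_h)
        local = t[mask] - seg.start_h
        dur = seg.end_h - seg.start_h
        # evaluate requested times and the segment end in one call
        eval_t = np.append(local, dur) if (local.size == 0 or local[-1] < dur) else local
        traj = solve_cascade(p, y_seg, eval_t)
        out[mask] = traj[: local.size]
        y_seg = np.maximum(traj[-1], 0.0)  # guard roundoff at the hand-over
    return out
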