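"""Seeded generators emulating the study's raw data types.

Three generators cover the pipeline's inputs so every stage can be
exercised without any download:

* :func:`gen_timecourse` — normalized Northern-blot band-intensity time
  courses following the heat/recovery sampling design (heat 2/3/4/5/6/8/24 h,
  recovery +2/3/6/8/24 h; probes p23/p43/p6 with probe-specific detection
  efficiencies), optionally with simulated 5S loading-control lanes.
* :func:`gen_trace` — two-peak sucrose-gradient A254 profiles as Gaussian
  mixtures on a drifting baseline.
* :func:`gen_counts` — multinomial category counts (e.g. nucleolus classes).

Every generator is a pure function of its parameters and the seed carried
by the :class:`NoiseModel`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .kinetics import (
    SPECIES,
    RateParameters,
    RegimeSchedule,
    Segment,
    simulate_schedule,
    steady_state,
)
from .profiles import AbsorbanceTrace


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise specification.

    kind : "none" | "lognormal-multiplicative" | "gaussian-additive"
    cv : coefficient of variation of the multiplicative factor (lognormal)
    sd : standard deviation of the additive term (gaussian)
    seed : RNG seed; a fixed seed makes the generated data reproducible
    """

    kind: str = "none"
    cv: float = 0.0
    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "lognormal-multiplicative", "gaussian-additive"):
            raise DataError(f"invalid noise level: unknown kind {self.kind!r}")
        if self.cv < 0 or self.sd < 0:
            raise DataError("invalid noise level: CV/sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or (self.cv == 0 and self.sd == 0):
            return np.asarray(values, dtype=float)
        if self.kind == "lognormal-multiplicative":
            # unit-mean multiplicative factor with the requested CV
            s2 = np.log1p(self.cv**2)
            factors = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2), size=np.shape(values))
            return values * factors
        return values + rng.normal(0.0, self.sd, size=np.shape(values))


# --- study-condition defaults -------------------------------------------------

#: Heat-phase sampling times (h), heat applied from t = 0.
HEAT_TIMES = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 24.0)
#: Recovery sampling times (h after return to 22°C at t = 24 h).
RECOVERY_OFFSETS = (2.0, 3.0, 6.0, 8.0, 24.0)

#: Probe-specific detection efficiencies (membrane/probe dependent).
DEFAULT_PROBE_SCALES = {"p23": 1.0, "p43": 1.4, "p6": 0.7}


def default_schedule() -> RegimeSchedule:
    """Heat 0–24 h at 37°C, then recovery 24–48 h at 22°C."""
    return RegimeSchedule(
        [Segment(0.0, 24.0, "heat37"), Segment(24.0, 48.0, "recovery22")]
    )


def default_times() -> list[float]:
    return list(HEAT_TIMES) + [24.0 + o for o in RECOVERY_OFFSETS]


def default_true_params() -> dict[str, RateParameters]:
    """Generating parameters for fixtures, chosen to sit inside the
    heat-response ranges the analysis is meant to resolve.

    Relative to baseline these give a 70% reduction of k45, a 35.7%
    reduction of the 35S→P-A3 transformation rate α·k35 (4.0×10⁻⁵ s⁻¹ at
    37°C), and a 2.5-fold increase of the P-A3 removal rate.  The 37°C
    synthesis flux is lowered so that the 45S pool rises (slower P-site
    cleavage dominates) while the 35S pool falls, mirroring the qualitative
    blot behaviour.
    """
    baseline = RateParameters(sigma=1.0, k45=0.2, k35=0.28, alpha=0.8, kpa3=0.3)
    heat = RateParameters(sigma=0.6, k45=0.06, k35=0.18, alpha=0.8, kpa3=0.75)
    return {"baseline22": baseline, "heat37": heat, "recovery22": baseline}


def default_design() -> dict:
    return {
        "times": default_times(),
        "probes": list(DEFAULT_PROBE_SCALES),
        "probe_scales": dict(DEFAULT_PROBE_SCALES),
        "replicates": 1,
    }


def gen_timecourse(
    params_by_regime: Mapping[str, RateParameters] | None = None,
    schedule: RegimeSchedule | None = None,
    design: Mapping | None = None,
    noise: NoiseModel | None = None,
    with_bands: bool = False,
    control_level: float = 100.0,
):
    """Simulate a normalized band-intensity time course (optionally raw bands).

    ``value = probe_scale × model trajectory × noise``; with no noise the
    table equals the model exactly.  ``params_by_regime`` must include
    ``baseline22`` (initial steady state) and one entry per schedule regime.

    Returns the tidy time-course DataFrame, or ``(timecourse, bands)`` when
    ``with_bands`` is set; the band table carries simulated 5S controls such
    that loading-control normalization reproduces the time course.
    """
    params = dict(params_by_regime or default_true_params())
    sched = schedule or default_schedule()
    des = dict(default_design())
    if design:
        des.update(design)
    noise = noise or NoiseModel()
    times = sorted(float(t) for t in des["times"])
    if not times:
        raise DataError("empty design: no sampling times")
    probes = list(des["probes"])
    if not probes:
        raise DataError("empty design: no probes")
    scales = des["probe_scales"]
    n_rep = int(des.get("replicates", 1))

    if "baseline22" not in params:
        raise DataError("unparameterized regime: baseline22 (initial condition)")
    y0 = steady_state(params["baseline22"])
    traj = simulate_schedule(sched, params, y0, times)

    rng = noise.rng()
    rows = []
    for rep in range(1, n_rep + 1):
        for probe in probes:
            clean = scales[probe] * traj  # (nt, 3)
            noisy = noise.apply(clean, rng)
            for i, t in enumerate(times):
                for j, sp in enumerate(SPECIES):
                    rows.append(
                        {
                            "time_h": t,
                            "species": sp,
                            "probe": probe,
                            "replicate": rep,
                            "value": float(noisy[i, j]),
                            "regime": sched.regime_at(t),
                        }
                    )
    tc = pd.DataFrame(rows)
    if not with_bands:
        return tc

    # raw bands: lane = (replicate, time); 5S control jitters around control_level
    ctrl_noise = NoiseModel("lognormal-multiplicative", cv=0.05, seed=noise.seed + 1)
    crng = ctrl_noise.rng()
    lanes = {}
    band_rows = []
    for _, row in tc.iterrows():
        lane_key = (row["replicate"], row["time_h"])
        if lane_key not in lanes:
            lanes[lane_key] = float(
                ctrl_noise.apply(np.array(control_level), crng)
            )
        ctrl = lanes[lane_key]
        band_rows.append(
            {
                "lane": f"rep{row['replicate']}_t{row['time_h']:g}",
                "condition": row["regime"],
                "time_h": row["time_h"],
                "probe": row["probe"],
                "species": row["species"],
                "intensity": row["value"] * ctrl,
                "control_intensity": ctrl,
                "replicate": row["replicate"],
            }
        )
    return tc, pd.DataFrame(band_rows)


def gen_trace(
    peaks: Sequence[tuple[float, float, float]],
    drift: tuple[float, float] = (0.0, 0.0),
    noise: NoiseModel | None = None,
    grid: np.ndarray | None = None,
) -> AbsorbanceTrace:
    """Gaussian-mixture gradient trace: sum of (center, width, area) peaks on a
    linear baseline ``drift = (intercept, slope)`` plus optional noise."""
    noise = noise or NoiseModel()
    x = np.linspace(0.0, 100.0, 1001) if grid is None else np.asarray(grid, float)
    if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
        raise DataError("invalid peak spec: grid must be 1-d strictly increasing")
    y = drift[0] + drift[1] * x
    for center, width, area in peaks:
        if width <= 0:
            raise DataError("invalid peak spec: zero width")
        y = y + area / (width * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - center) / width) ** 2
        )
    y = noise.apply(y, noise.rng())
    return AbsorbanceTrace(x, y)


def gen_spectral_counts(
    class_totals: Mapping[str, float],
    fractions: Sequence[str],
    proteins_per_class: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Synthetic weighted-spectral-count table with known class composition.

    Each ribosomal-protein class's total weighted count is split across
    ``proteins_per_class`` synthetic protein ids and the given fractions with
    Dirichlet-distributed weights, so pooling all fractions and summing per
    class recovers ``class_totals`` exactly.

    Returns the spectra table (protein, fraction, count) and the matching
    protein → class annotation map.
    """
    if not fractions:
        raise DataError("empty group: no fractions")
    rng = np.random.default_rng(seed)
    rows = []
    annotation: dict[str, str] = {}
    for cls, total in class_totals.items():
        if total < 0:
            raise DataError("invalid proportions: negative count")
        ids = [f"{cls}-syn{i + 1}" for i in range(proteins_per_class)]
        weights = rng.dirichlet(np.ones(proteins_per_class * len(fractions)))
        k = 0
        for pid in ids:
            annotation[pid] = cls
            for frac in fractions:
                rows.append(
                    {"protein": pid, "fraction": frac, "count": total * weights[k]}
                )
                k += 1
    return pd.DataFrame(rows), annotation


def gen_counts(
    proportions: Mapping[str, float] | Sequence[float],
    n: int,
    seed: int,
) -> pd.Series:
    """Multinomial category counts with the given true proportions.

    Returns a Series indexed by category name (auto-named ``cat1..catk`` for
    unnamed sequences); deterministic given ``seed``.
    """
    if isinstance(proportions, Mapping):
        names = list(proportions)
        p = np.array([proportions[k] for k in names], dtype=float)
    else:
        p = np.asarray(proportions, dtype=float)
        names = [f"cat{i + 1}" for i in range(p.size)]
    if np.any(p < 0) or p.size == 0 or abs(p.sum() - 1.0) > 1e-9:
        raise DataError("invalid proportions: must be >= 0 and sum to 1")
    if n < 0:
        raise DataError("invalid proportions: n must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p)
    return pd.Series(counts, index=names, name="count")
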