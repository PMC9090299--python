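"""Densitometry normalization, primer-extension ratios and 45S map classification.

Band intensities from Northern blots are corrected for loaded RNA amount by
dividing by the 5S rRNA signal of the same lane (loading-control
normalization).  Transcript 5'/3' end coordinates recovered by circular
RT-PCR are classified against the named processing sites of the 45S
pre-rRNA unit (1-based, transcription initiation site = +1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .kinetics import RegimeSchedule


@dataclass(frozen=True)
class Site:
    """A named landmark on the 45S unit: a point, a doublet, or an interval's
    two boundaries; ``coords`` holds the representative coordinates."""

    name: str
    coords: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.coords or any(c < 1 for c in self.coords):
            raise DataError("invalid site: coordinates must be positive")


class SiteMap:
    """Ordered collection of processing-site coordinates on the 45S unit."""

    def __init__(self, sites: Iterable[Site]):
        self.sites: tuple[Site, ...] = tuple(sites)
        names = [s.name for s in self.sites]
        if len(set(names)) != len(names):
            raise DataError("invalid site map: duplicate site names")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)


#: Processing-site coordinates of the Arabidopsis 45S rDNA unit, 1-based with
#: the transcription initiation site at +1.  Intervals (mature rRNAs) are
#: represented by their two boundary coordinates.
DEFAULT_SITE_MAP = SiteMap(
    [
        Site("TIS", (1,)),
        Site("P", (1274, 1275)),
        Site("P'", (1755,)),
        Site("18S", (1836, 3639)),
        Site("A2", (3661,)),
        Site("A3", (3830,)),
        Site("5.8S-5'", (3911,)),
        Site("25S", (4259, 7633)),
    ]
)

#: Default classification tolerance in nucleotides (the P site itself is a
#: two-position doublet).
DEFAULT_END_TOLERANCE = 2


class EndClassification(NamedTuple):
    label: str  # site name, or "unassigned"
    nearest: str  # nearest site name (== label when assigned)
    offset: int  # signed nt offset from the nearest site coordinate


def classify_fragment_end(
    coordinate: int,
    site_map: SiteMap = DEFAULT_SITE_MAP,
    tolerance: int = DEFAULT_END_TOLERANCE,
) -> EndClassification:
    """Assign a cRT-PCR-mapped transcript end to the nearest processing site.

    The end is labelled with the site whose coordinate (or interval boundary)
    lies within ``tolerance`` nt; ties are broken by smallest absolute offset,
    then by map order.  Otherwise the label is ``"unassigned"`` and the
    nearest site plus the signed offset are reported.
    """
    if len(site_map) == 0:
        raise DataError("no sites")
    if coordinate < 1:
        raise DataError("invalid coordinate: must be >= 1")
    if tolerance < 0:
        raise DataError("invalid tolerance: must be >= 0")
    best_name, best_off = None, None
    for site in site_map:
        off = min((coordinate - c for c in site.coords), key=abs)
        if best_off is None or abs(off) < abs(best_off):
            best_name, best_off = site.name, off
    if abs(best_off) <= tolerance:
        return EndClassification(best_name, best_name, int(best_off))
    return EndClassification("unassigned", best_name, int(best_off))


BAND_COLUMNS = (
    "lane",
    "condition",
    "time_h",
    "probe",
    "species",
    "intensity",
    "control_intensity",
)


def normalize_to_control(
    bands: pd.DataFrame, rescale_to_t0: bool = False
) -> pd.DataFrame:
    """Divide each band intensity by its lane's 5S loading-control signal.

    Parameters
    ----------
    bands : DataFrame
        Columns :data:`BAND_COLUMNS` (plus optional ``replicate``); one row
        per band, with the 5S signal of the same lane alongside.
    rescale_to_t0 : bool
        If True, additionally rescale each (probe, species) series to its
        t = 0 value (off by default).

    Returns
    -------
    DataFrame
        Tidy time-course table: ``time_h, species, probe, replicate, value``.
    """
    missing = [c for c in BAND_COLUMNS if c not in bands.columns]
    if missing:
        raise DataError(f"schema mismatch: {missing[0]}")
    ctrl = bands["control_intensity"]
    if ctrl.isna().any() or (ctrl <= 0).any():
        raise DataError("loading control missing: control intensity must be > 0")
    if bands["intensity"].lt(0).any():
        raise DataError("invalid observations: band intensity must be >= 0")
    key = ["lane", "probe", "species"]
    if bands.duplicated(subset=key).any():
        raise DataError("conflicting observations: duplicate (lane, probe, species)")
    out = bands.copy()
    out["value"] = out["intensity"] / ctrl
    out["replicate"] = out["replicate"] if "replicate" in out.columns else 1
    out = out[["time_h", "species", "probe", "replicate", "value"]].reset_index(
        drop=True
    )
    if rescale_to_t0:
        def _rescale(g: pd.DataFrame) -> pd.DataFrame:
            ref = g.loc[g["time_h"] == 0.0, "value"]
            if ref.empty or (ref <= 0).all():
                raise DataError("loading control missing: no positive t=0 reference")
            g = g.copy()
            g["value"] = g["value"] / ref.mean()
            return g

        out = (
            out.groupby(["probe", "species"], group_keys=False)[out.columns]
            .apply(_rescale)
            .reset_index(drop=True)
        )
    return out


class FoldChange(NamedTuple):
    fold: float
    nearest_int: int


def tis_p_fold_change(ratio_22: float, ratio_37: float) -> FoldChange:
    """Fold change of the TIS/P primer-extension signal ratio, 37°C over 22°C.

    The TIS/P ratio reports the balance between transcription initiation and
    primary cleavage at the P site; its fold change under heat stress is
    reported both exactly and rounded to the nearest integer.
    """
    if ratio_22 <= 0 or ratio_37 <= 0:
        raise DataError("undefined fold change: ratios must be > 0")
    fold = ratio_37 / ratio_22
    return FoldChange(fold, int(round(fold)))


def build_timecourse(
    tables: Sequence[pd.DataFrame] | pd.DataFrame,
    schedule: RegimeSchedule | None = None,
) -> pd.DataFrame:
    """Merge replicate/probe time-course tables into one fit observable.

    Duplicate (time, species, probe, replicate) rows across inputs raise
    "conflicting observations".  If a schedule is given, a ``regime`` column
    is attached from it.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    if not tables:
        raise DataError("empty table")
    merged = pd.concat(tables, ignore_index=True)
    for col in ("time_h", "species", "probe", "replicate", "value"):
        if col not in merged.columns:
            raise DataError(f"schema mismatch: {col}")
    key = ["time_h", "species", "probe", "replicate"]
    if merged.duplicated(subset=key).any():
        raise DataError("conflicting observations: duplicate observation rows")
    if (merged["time_h"] < 0).any():
        raise DataError("invalid observations: negative time")
    if schedule is not None:
        merged = merged.copy()
        merged["regime"] = merged["time_h"].map(schedule.regime_at)
    return merged.reset_index(drop=True)
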