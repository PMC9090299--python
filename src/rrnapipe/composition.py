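"""Categorical composition statistics.

Two kinds of category counts flow through this module: nucleolus
morphology classes scored from electron micrographs (class I intact,
class II partially disrupted, class III open/collapsed), and weighted
spectral counts of ribosomal proteins (RPS small subunit, RPL large
subunit, RPP P-stalk phosphoproteins) summed over sucrose-gradient
fraction pools.  Counts may be non-integer when weighted.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .errors import DataError

RP_CLASSES = ("RPS", "RPL", "RPP")
OTHER_CLASS = "other"


def category_proportions(counts: Mapping[str, float]) -> dict[str, float]:
    """Percentages per category for one group, rounded to one decimal.

    The rounded values are re-checked to sum to 100 ± 0.2.
    """
    if not counts:
        raise DataError("empty group")
    vals = np.array(list(counts.values()), dtype=float)
    if np.any(vals < 0):
        raise DataError("invalid proportions: negative count")
    total = vals.sum()
    if total <= 0:
        raise DataError("empty group")
    pct = {k: round(100.0 * v / total, 1) for k, v in counts.items()}
    if abs(sum(pct.values()) - 100.0) > 0.2:
        raise DataError("invalid proportions: rounded percentages drift beyond 0.2")
    return pct


def pool_and_classify(
    spectra: pd.DataFrame,
    annotation: Mapping[str, str],
    pools: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Sum weighted spectral counts per ribosomal-protein class and fraction pool.

    Parameters
    ----------
    spectra : DataFrame
        Columns ``protein, fraction, count`` — weighted spectral counts as
        exported by the search-result software.
    annotation : mapping
        protein id → class in {RPS, RPL, RPP}; ids absent from the map are
        counted under "other" (with a warning) and excluded from
        ribosomal-protein percentages downstream.
    pools : mapping
        pool label → collection of fraction labels (e.g. the 40S pool is
        fractions 8 + 9 at 22°C).

    Returns
    -------
    DataFrame
        Columns ``group, category, count`` with one row per (pool, class).
    """
    for col in ("protein", "fraction", "count"):
        if col not in spectra.columns:
            raise DataError(f"schema mismatch: {col}")
    if (spectra["count"] < 0).any():
        raise DataError("invalid proportions: negative count")
    classes = spectra["protein"].map(lambda p: annotation.get(p, OTHER_CLASS))
    unmapped = sorted(set(spectra.loc[classes == OTHER_CLASS, "protein"]))
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} protein id(s) missing from the annotation map, "
            f"counted as 'other': {unmapped[:5]}",
            UserWarning,
            stacklevel=2,
        )
    bad = [c for c in classes.unique() if c not in RP_CLASSES + (OTHER_CLASS,)]
    if bad:
        raise DataError(f"invalid proportions: unknown protein class {bad[0]!r}")
    work = spectra.assign(category=classes)
    rows = []
    for pool, fracs in pools.items():
        sub = work[work["fraction"].isin(set(fracs))]
        if sub.empty:
            raise DataError(f"empty group: pool {pool!r} matches no fractions")
        sums = sub.groupby("category")["count"].sum()
        for cls in RP_CLASSES + (OTHER_CLASS,):
            if cls in sums.index:
                rows.append({"group": pool, "category": cls, "count": float(sums[cls])})
    return pd.DataFrame(rows)


def ribosomal_proportions(pooled: pd.DataFrame, group: str) -> dict[str, float]:
    """Percentages of RPS/RPL/RPP within one pool, excluding the 'other' class."""
    sub = pooled[(pooled["group"] == group) & (pooled["category"] != OTHER_CLASS)]
    if sub.empty:
        raise DataError("empty group")
    return category_proportions(dict(zip(sub["category"], sub["count"])))


def compare_distributions(
    counts_a: Mapping[str, float], counts_b: Mapping[str, float]
) -> tuple[float, int, float]:
    """Pearson chi-square (uncorrected) comparing two category distributions.

    Returns (statistic, degrees of freedom, p-value) for the 2×k table.
    Provided as a convenience for shifts the source data report descriptively.
    """
    if set(counts_a) != set(counts_b):
        raise DataError("test undefined; pool categories: category sets differ")
    cats = list(counts_a)
    table = np.array([[counts_a[c] for c in cats], [counts_b[c] for c in cats]])
    if np.any(table < 0):
        raise DataError("invalid proportions: negative count")
    if table.sum() <= 0 or np.any(table.sum(axis=0) == 0) or np.any(
        table.sum(axis=1) == 0
    ):
        raise DataError("test undefined; pool categories: zero expected cell")
    stat, p, dof, expected = chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise DataError("test undefined; pool categories: zero expected cell")
    return float(stat), int(dof), float(p)
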