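"""Range-change, persistence, protected-area and refugia metrics.

Suitability maps are thresholded at the species-specific cut-off that
maximised sensitivity + specificity, and compared across time periods
and regional climate models (RCMs):

* % change in suitable area — 100 x (future - present) / present cells;
* % overlap — 100 x (cells suitable now and in future) / present cells,
  a measure of in-place resilience;
* % change in mean suitability — 100 x mean(future) / mean(present) on
  the continuous maps, so < 100 means declining suitability (high
  vulnerability) and > 100 increasing suitability.  The complementary
  "decrease by" figure 100 - ratio is reported alongside under its own
  label to avoid conflating the two conventions.

Differences between periods across the RCM replicates are tested with an
exact two-sided Wilcoxon rank-sum test (full enumeration at small n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .ensemble import SuitabilityMap
from .grids import Grid, ProtectedAreas
from .occurrences import PRESENCE, OccurrenceSet

__all__ = [
    "RangeMap",
    "ChangeSummary",
    "binarize",
    "suitable_area",
    "pct_change_area",
    "pct_overlap",
    "pct_mean_suitability",
    "persistence_at_points",
    "protected_overlap",
    "refugia",
    "wilcoxon_exact",
    "summarise_change",
]


@dataclass
class RangeMap:
    """Thresholded presence-absence map on land cells."""

    mask: Grid  # 1.0 suitable, 0.0 unsuitable, NaN sea
    threshold: int = 0
    species: str = ""
    period: str = "present"
    rcm: str = "observed"

    @property
    def suitable(self) -> np.ndarray:
        """Boolean array: land cells at or above the threshold."""
        return np.nan_to_num(self.mask.values, nan=0.0) > 0.5

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())


def binarize(smap: SuitabilityMap, threshold: int) -> RangeMap:
    """Suitable wherever suitability >= threshold (0-1000 scale)."""
    if not 0 <= threshold <= 1000:
        raise ValueError("threshold must be on the 0-1000 scale")
    g = smap.grid
    vals = np.where(g.mask, (g.values >= threshold).astype(float), np.nan)
    return RangeMap(
        mask=g.copy_with(vals),
        threshold=int(threshold),
        species=smap.species,
        period=smap.period,
        rcm=smap.rcm,
    )


def suitable_area(rmap: RangeMap) -> float:
    """Total suitable area in squared map units (cells x cell area)."""
    return rmap.n_suitable * rmap.mask.cell_size**2


def _check_registered(a: Grid, b: Grid) -> None:
    if not a.same_geometry(b):
        raise ValueError("maps must be co-registered")


def pct_change_area(present: RangeMap, future: RangeMap) -> float:
    """100 x (future - present) suitable cells / present suitable cells."""
    _check_registered(present.mask, future.mask)
    n0 = present.n_suitable
    if n0 == 0:
        raise ValueError("present range is empty; % change in area undefined")
    return 100.0 * (future.n_suitable - n0) / n0


def pct_overlap(present: RangeMap, future: RangeMap) -> float:
    """Percentage of presently suitable cells that stay suitable."""
    _check_registered(present.mask, future.mask)
    n0 = present.n_suitable
    if n0 == 0:
        raise ValueError("present range is empty; % overlap undefined")
    return 100.0 * (present.suitable & future.suitable).sum() / n0


def pct_mean_suitability(present: SuitabilityMap, future: SuitabilityMap) -> float:
    """100 x mean(future suitability) / mean(present suitability) over land."""
    _check_registered(present.grid, future.grid)
    m0 = present.grid.land_values().mean()
    if m0 <= 0:
        raise ValueError("present mean suitability is zero; ratio undefined")
    return 100.0 * future.grid.land_values().mean() / m0


def persistence_at_points(points: OccurrenceSet, future: RangeMap) -> float:
    """Percentage of presence points whose cell stays suitable."""
    pres = points.records[points.records["label"] == PRESENCE]
    if not len(pres):
        raise ValueError("no presence points to track")
    g = future.mask
    row, col = g.cell_index(pres["x"].to_numpy(), pres["y"].to_numpy())
    inside = (row >= 0) & (row < g.nrows) & (col >= 0) & (col < g.ncols)
    ok = np.zeros(len(pres), dtype=bool)
    ok[inside] = future.suitable[row[inside], col[inside]]
    return 100.0 * ok.sum() / len(pres)


def protected_overlap(rmap: RangeMap, pa: ProtectedAreas, network: str) -> float:
    """Percentage of suitable cells lying inside a protected-area network."""
    mask = pa[network]
    _check_registered(rmap.mask, mask)
    n = rmap.n_suitable
    if n == 0:
        raise ValueError("range map has no suitable cells")
    protected = np.nan_to_num(mask.values, nan=0.0) > 0.5
    return 100.0 * (rmap.suitable & protected).sum() / n


def refugia(future_maps: list[RangeMap], rule: str = "majority") -> Grid:
    """Cells suitable in the final period under an across-RCM agreement rule.

    ``majority`` (default): suitable in more than half of the RCMs;
    ``any`` / ``all``: union / intersection.
    """
    if not future_maps:
        raise ValueError("no range maps supplied")
    template = future_maps[0].mask
    for m in future_maps[1:]:
        _check_registered(template, m.mask)
    counts = np.sum([m.suitable for m in future_maps], axis=0)
    k = len(future_maps)
    if rule == "majority":
        agreed = counts >= (k // 2 + 1)
    elif rule == "any":
        agreed = counts >= 1
    elif rule == "all":
        agreed = counts == k
    else:
        raise ValueError(f"unknown agreement rule {rule!r}")
    return template.copy_with(np.where(template.mask, agreed.astype(float), np.nan))


# ----------------------------------------------------------------------
def wilcoxon_exact(group_a, group_b) -> float:
    """Exact two-sided Wilcoxon rank-sum p-value by full enumeration.

    All C(n_a + n_b, n_a) assignments of the (mid)ranks to group A are
    enumerated and the two-sided p is twice the smaller tail probability
    of the observed rank sum, capped at 1.  Midranks handle ties, and
    monotone transforms of the data leave p unchanged.  Beyond 12 total
    observations the normal approximation is used with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    if n_a + n_b > 12:
        import warnings

        warnings.warn("wilcoxon_exact: large samples; using the normal approximation")
        return float(stats.ranksums(a, b).pvalue)
    ranks = stats.rankdata(np.concatenate([a, b]))  # midranks for ties
    w_obs = ranks[:n_a].sum()
    total = comb(n_a + n_b, n_a)
    le = ge = 0
    for idx in combinations(range(n_a + n_b), n_a):
        w = ranks[list(idx)].sum()
        if w <= w_obs + 1e-9:
            le += 1
        if w >= w_obs - 1e-9:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return float(min(p, 1.0))


@dataclass
class ChangeSummary:
    """Per-RCM metric values with mean +/- standard error for one period."""

    period: str
    per_rcm: pd.DataFrame  # columns: rcm, metric, value
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        rows = []
        for metric, grp in self.per_rcm.groupby("metric", sort=True):
            v = grp["value"].to_numpy(dtype=float)
            sd = v.std(ddof=1) if v.size > 1 else 0.0
            rows.append(
                {
                    "period": self.period,
                    "metric": metric,
                    "mean": float(v.mean()),
                    "se": float(sd / np.sqrt(v.size)),
                    "n_rcm": int(v.size),
                }
            )
        self.summary = pd.DataFrame(rows)

    def mean_of(self, metric: str) -> float:
        row = self.summary[self.summary["metric"] == metric]
        if not len(row):
            raise KeyError(f"no such metric {metric!r}")
        return float(row["mean"].iloc[0])


def summarise_change(per_rcm_values: dict[str, dict[str, float]], period: str) -> ChangeSummary:
    """Summarise {metric: {rcm: value}} into a ChangeSummary for a period."""
    rows = [
        {"rcm": rcm, "metric": metric, "value": float(v)}
        for metric, by_rcm in per_rcm_values.items()
        for rcm, v in by_rcm.items()
    ]
    if not rows:
        raise ValueError("no per-RCM values supplied")
    df = pd.DataFrame(rows)
    counts = df.groupby("metric")["rcm"].count()
    if (counts < 2).any():
        raise ValueError("each metric needs values from at least 2 RCMs")
    return ChangeSummary(period=period, per_rcm=df)
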