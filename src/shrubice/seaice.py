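"""Sea-ice extent series and retreat/advance phenology.

Monthly sea-ice extent (SIE, 10^6 km^2) per region is the basic input.
Gap months are filled with the arithmetic mean of the same calendar
month in the two adjacent years.  Seasonal variables are means of named
month sets; a leading ``p`` marks months drawn from the year before the
growth year (e.g. ``pSON`` for year t averages Sep-Nov of t-1).

Phenology works on daily sea-ice concentration (SIC, %) grids for one
ice year per region: for every cell the *last retreat day* (LRD) is the
final day concentration drops below the threshold before the day of
annual minimum extent, and the *first advance day* (FAD) is the first
day it comes back above the threshold afterwards.  Cells that never
experience both crossings (perennially ice-covered or ice-free) are
excluded; regional LRD/FAD are area-weighted means over the rest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MonthlyIceSeries",
    "Season",
    "DEFAULT_SEASONS",
    "IceConcentrationGrid",
    "IcePhenology",
    "read_monthly_extent",
    "write_monthly_extent",
    "fill_monthly_gaps",
    "seasonal_aggregate",
    "monthly_variable",
    "ice_phenology",
    "phenology_series",
    "zscore",
]


@dataclass
class MonthlyIceSeries:
    """Monthly sea-ice extent records for one region."""

    region_id: str
    records: pd.DataFrame  # columns: year, month, extent
    filled_months: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.records[["year", "month", "extent"]].copy()
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        if df.duplicated(["year", "month"]).any():
            raise ValueError(f"{self.region_id}: duplicate (year, month) records")
        if (df["extent"] < 0).any():
            raise ValueError(f"{self.region_id}: negative extents")
        self.records = df.sort_values(["year", "month"]).reset_index(drop=True)

    def lookup(self) -> dict[tuple[int, int], float]:
        return {
            (int(r.year), int(r.month)): float(r.extent)
            for r in self.records.itertuples(index=False)
        }

    @property
    def span(self) -> tuple[tuple[int, int], tuple[int, int]]:
        first = self.records.iloc[0]
        last = self.records.iloc[-1]
        return (int(first.year), int(first.month)), (int(last.year), int(last.month))


def read_monthly_extent(path: str | Path) -> dict[str, MonthlyIceSeries]:
    """Read delimited monthly extent (region_id, year, month, extent_1e6km2)."""
    df = pd.read_csv(path, sep=None, engine="python")
    col = "extent_1e6km2" if "extent_1e6km2" in df.columns else "extent"
    out = {}
    for rid, grp in df.groupby("region_id"):
        out[str(rid)] = MonthlyIceSeries(
            str(rid), grp.rename(columns={col: "extent"})[["year", "month", "extent"]]
        )
    return out


def write_monthly_extent(series: Mapping[str, MonthlyIceSeries], path: str | Path) -> None:
    rows = []
    for rid in sorted(series):
        df = series[rid].records.copy()
        df.insert(0, "region_id", rid)
        rows.append(df)
    pd.concat(rows).rename(columns={"extent": "extent_1e6km2"}).to_csv(path, index=False)


def _month_iter(start: tuple[int, int], end: tuple[int, int]):
    y, m = start
    while (y, m) <= end:
        yield y, m
        m += 1
        if m == 13:
            y, m = y + 1, 1


def fill_monthly_gaps(s: MonthlyIceSeries) -> MonthlyIceSeries:
    """Fill missing months inside the span from the adjacent years.

    A missing (year, m) is replaced by the mean of (year-1, m) and
    (year+1, m).  Gaps at the span edge, or whose neighbours are also
    missing, raise ``ValueError`` naming the month.
    """
    have = s.lookup()
    start, end = s.span
    filled = []
    rows = []
    for y, m in _month_iter(start, end):
        if (y, m) in have:
            rows.append((y, m, have[(y, m)]))
            continue
        prev, nxt = have.get((y - 1, m)), have.get((y + 1, m))
        if prev is None or nxt is None:
            raise ValueError(f"{s.region_id}: cannot fill gap at {y}-{m:02d} from adjacent years")
        rows.append((y, m, 0.5 * (prev + nxt)))
        filled.append((y, m))
    df = pd.DataFrame(rows, columns=["year", "month", "extent"])
    return MonthlyIceSeries(s.region_id, df, filled_months=list(s.filled_months) + filled)


@dataclass(frozen=True)
class Season:
    """A named month set; each month carries a year offset (0 or -1)."""

    name: str
    months: tuple[tuple[int, int], ...]  # (month, year_offset)


DEFAULT_SEASONS: dict[str, Season] = {
    "JJA": Season("JJA", ((6, 0), (7, 0), (8, 0))),
    "MAM": Season("MAM", ((3, 0), (4, 0), (5, 0))),
    "pSON": Season("pSON", ((9, -1), (10, -1), (11, -1))),
    "pDJF": Season("pDJF", ((12, -1), (1, 0), (2, 0))),
    "annual": Season("annual", tuple((m, 0) for m in range(1, 13))),
}


def seasonal_aggregate(s: MonthlyIceSeries, season: Season | str) -> pd.Series:
    """Per-year arithmetic mean of the season's months.

    A year whose constituent months are not all present is omitted
    (never a partial mean).
    """
    if isinstance(season, str):
        try:
            season = DEFAULT_SEASONS[season]
        except KeyError:
            raise ValueError(f"unknown season {season!r}") from None
    have = s.lookup()
    years = sorted({y for (y, _m) in have})
    out = {}
    for t in years:
        vals = [have.get((t + off, m)) for m, off in season.months]
        if all(v is not None for v in vals):
            out[t] = float(np.mean(vals))
    ser = pd.Series(out, dtype=float)
    ser.index.name = "year"
    ser.name = f"{s.region_id}:{season.name}"
    return ser


def monthly_variable(s: MonthlyIceSeries, month: int, previous: bool = False) -> pd.Series:
    """One calendar month as a per-year series, optionally previous-year aligned."""
    off = -1 if previous else 0
    name = f"{s.region_id}:{'p' if previous else ''}M{month:02d}"
    have = s.lookup()
    out = {t: have[(t + off, month)] for t in sorted({y for (y, _m) in have}) if (t + off, month) in have}
    ser = pd.Series(out, dtype=float)
    ser.index.name = "year"
    ser.name = name
    return ser


@dataclass
class IceConcentrationGrid:
    """Daily SIC for one region and ice year.

    ``days`` are 1-based days of the ice year; ``conc`` is (n_days,
    n_cells) in percent; ``cell_area`` in km^2.
    """

    days: np.ndarray
    conc: np.ndarray
    cell_area: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, int)
        self.conc = np.asarray(self.conc, float)
        self.cell_area = np.asarray(self.cell_area, float)
        if self.conc.shape != (self.days.size, self.cell_area.size):
            raise ValueError("conc must be (n_days, n_cells)")
        if np.any((self.conc < 0) | (self.conc > 100)):
            raise ValueError("concentrations must lie in [0, 100]")
        if np.any(self.cell_area <= 0):
            raise ValueError("cell areas must be positive")


def read_concentration_grid(path: str | Path) -> IceConcentrationGrid:
    """Read a long-format grid table (day, cell_id, concentration, cell_area)."""
    df = pd.read_csv(path, sep=None, engine="python")
    wide = df.pivot(index="day", columns="cell_id", values="concentration").sort_index()
    areas = df.groupby("cell_id")["cell_area"].first().reindex(wide.columns)
    return IceConcentrationGrid(wide.index.to_numpy(), wide.to_numpy(), areas.to_numpy())


@dataclass
class IcePhenology:
    """Per-year retreat/advance days for one region at one SIC threshold."""

    region_id: str
    years: np.ndarray
    lrd: np.ndarray  # day of year, 1-based
    fad: np.ndarray
    threshold: float = 50.0

    def frame(self) -> pd.DataFrame:
        idx = pd.Index(self.years, name="year")
        df = pd.DataFrame({"lrd_doy": self.lrd, "fad_doy": self.fad}, index=idx)
        df["lrd_z"] = zscore(df["lrd_doy"])
        df["fad_z"] = zscore(df["fad_doy"])
        return df


def ice_phenology(grid: IceConcentrationGrid, threshold: float = 50.0) -> tuple[float, float]:
    """Area-weighted (LRD, FAD) for one region-year.

    The pivot is the day of minimum extent at ``threshold``.  Per cell,
    retreat day is the last crossing from >= threshold to < threshold at
    or before the pivot, and advance day the first crossing back to
    >= threshold after it.  Cells lacking either crossing are excluded.
    """
    if not 0 < threshold < 100:
        raise ValueError("threshold must be in (0, 100)")
    above = grid.conc >= threshold
    extent = (above * grid.cell_area).sum(axis=1)
    pivot = int(np.argmin(extent))

    lrds, fads, weights = [], [], []
    for c in range(grid.cell_area.size):
        a = above[:, c]
        down = np.flatnonzero(~a[1:] & a[:-1]) + 1  # first day below
        up = np.flatnonzero(a[1:] & ~a[:-1]) + 1    # first day back above
        down = down[down <= pivot]
        up = up[up > pivot]
        if down.size == 0 or up.size == 0:
            continue
        lrds.append(grid.days[down[-1]])
        fads.append(grid.days[up[0]])
        weights.append(grid.cell_area[c])
    if not weights:
        raise ValueError("no seasonal ice zone: no cell experienced both retreat and advance")
    w = np.asarray(weights, float)
    return float(np.average(lrds, weights=w)), float(np.average(fads, weights=w))


def phenology_series(
    grids: Mapping[int, IceConcentrationGrid],
    region_id: str,
    threshold: float = 50.0,
) -> IcePhenology:
    """LRD/FAD time series over ice years from per-year grids."""
    years = sorted(grids)
    lrd, fad = [], []
    for y in years:
        l, f = ice_phenology(grids[y], threshold)
        lrd.append(l)
        fad.append(f)
    return IcePhenology(region_id, np.array(years), np.array(lrd), np.array(fad), threshold)


def zscore(x: pd.Series | np.ndarray, period: tuple[int, int] | None = None) -> pd.Series | np.ndarray:
    """Standardize to mean 0, sd 1 (population sd over the reference period)."""
    if isinstance(x, pd.Series):
        ref = x.loc[period[0] : period[1]] if period else x
        sd = float(ref.std(ddof=0))
        if sd == 0 or math.isnan(sd):
            raise ValueError("cannot z-score a constant series")
        return (x - float(ref.mean())) / sd
    arr = np.asarray(x, float)
    sd = arr.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant series")
    return (arr - arr.mean()) / sd
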