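"""Reading, writing and screening of shrub ring-width series.

Ring-width data travel in the Tucson/RWL decadal interchange format:
one or more lines per series, each carrying a series id, the calendar
year of the first value on the line, and up to ten integer-encoded
widths.  Two encodings are in common circulation and both are
supported, auto-detected per series from the stop marker:

* stop marker ``999``  — widths in units of 0.01 mm
* stop marker ``-9999`` — widths in units of 0.001 mm

Site-level metadata (species, soil moisture class, coordinates, sea-ice
region assignment) is not expressible in RWL and is carried in a sidecar
delimited table keyed by ``site_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RingSeries",
    "SeriesStats",
    "ScreenResult",
    "read_rwl",
    "write_rwl",
    "read_site_metadata",
    "attach_metadata",
    "series_stats",
    "screen_chronologies",
]

_STOP_001 = 999       # 0.01 mm dialect
_STOP_0001 = -9999    # 0.001 mm dialect


@dataclass
class RingSeries:
    """One cross-section's cross-dated annual ring widths (mm)."""

    series_id: str
    first_year: int
    widths: np.ndarray
    shrub_id: str = ""
    site_id: str = ""
    species: str = ""            # "Betula" or "Salix"
    soil_class: str = ""         # "dry" or "moist"
    latitude: float = math.nan
    longitude: float = math.nan
    ice_region_id: str = ""
    is_root_collar: bool = True

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1 or self.widths.size < 1:
            raise ValueError(f"series {self.series_id!r}: widths must be a non-empty 1-d array")
        if np.any(self.widths < 0) or not np.all(np.isfinite(self.widths)):
            raise ValueError(f"series {self.series_id!r}: widths must be finite and >= 0")

    @property
    def n_rings(self) -> int:
        return int(self.widths.size)

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_rings - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.n_rings)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RingSeries):
            return NotImplemented
        return (
            self.series_id == other.series_id
            and self.first_year == other.first_year
            and np.array_equal(self.widths, other.widths)
        )


@dataclass(frozen=True)
class SeriesStats:
    """Descriptive statistics of one ring-width series.

    ``ms`` is mean sensitivity, the mean absolute relative difference of
    consecutive widths; ``ar1`` the Pearson correlation of the series
    with itself at lag one (NaN when undefined, e.g. constant series).
    """

    n_rings: int
    ms: float
    ar1: float
    span: tuple[int, int]

    @property
    def ar1_defined(self) -> bool:
        return not math.isnan(self.ar1)


def _parse_int(tok: str, lineno: int) -> int:
    try:
        return int(tok)
    except ValueError:
        raise ValueError(f"RWL parse error at line {lineno}: non-integer field {tok!r}") from None


def read_rwl(path: str | Path) -> list[RingSeries]:
    """Read a Tucson/RWL decadal file into a list of :class:`RingSeries`.

    The measurement-unit dialect (0.01 mm vs 0.001 mm) is auto-detected
    per series from its stop marker.  Raises ``ValueError`` on malformed
    lines (with the line number), duplicate series ids, or an empty file.
    """
    path = Path(path)
    raw: dict[str, list[tuple[int, list[int], int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) < 3:
                raise ValueError(f"RWL parse error at line {lineno}: expected id, year and values")
            sid = toks[0]
            year = _parse_int(toks[1], lineno)
            vals = [_parse_int(t, lineno) for t in toks[2:]]
            if sid not in raw:
                raw[sid] = []
                order.append(sid)
            raw[sid].append((year, vals, lineno))

    if not order:
        raise ValueError(f"empty RWL file: {path}")

    out: list[RingSeries] = []
    for sid in order:
        out.append(_decode_series(sid, raw[sid]))
    return out


def _flatten(chunks: list[tuple[int, list[int], int]]) -> list[int]:
    return [v for _, vals, _ in chunks for v in vals]


def _decode_series(sid: str, chunks: list[tuple[int, list[int], int]]) -> RingSeries:
    allvals = _flatten(chunks)
    if _STOP_0001 in allvals:
        precision, stop = 0.001, _STOP_0001
    elif _STOP_001 in allvals:
        precision, stop = 0.01, _STOP_001
    else:
        raise ValueError(f"series {sid!r}: no stop marker (999 or -9999) found")

    first_year = chunks[0][0]
    widths: list[float] = []
    expect_year = first_year
    done = False
    for year, vals, lineno in chunks:
        if done:
            raise ValueError(
                f"series {sid!r}: duplicate series id / data after stop marker at line {lineno}"
            )
        if year != expect_year:
            raise ValueError(
                f"RWL parse error at line {lineno}: series {sid!r} year {year} "
                f"not contiguous (expected {expect_year})"
            )
        for v in vals:
            if v == stop:
                done = True
                break
            widths.append(v * precision)
        if not done:
            expect_year = year + len(vals)
    if not done:
        raise ValueError(f"series {sid!r}: missing stop marker")
    if not widths:
        raise ValueError(f"series {sid!r}: no measurements before stop marker")
    return RingSeries(series_id=sid, first_year=first_year, widths=np.array(widths))


def write_rwl(series: Sequence[RingSeries], path: str | Path, precision: float = 0.01) -> None:
    """Write series to Tucson/RWL decadal format.

    ``precision`` selects the dialect: 0.01 mm (stop 999) or 0.001 mm
    (stop -9999).  Lines are decade-aligned after the first.
    """
    if precision not in (0.01, 0.001):
        raise ValueError("precision must be 0.01 or 0.001")
    stop = _STOP_001 if precision == 0.01 else _STOP_0001
    path = Path(path)
    with open(path, "w") as fh:
        for s in series:
            vals = [int(round(w / precision)) for w in s.widths] + [stop]
            year = s.first_year
            i = 0
            while i < len(vals):
                # fill to the end of the current decade
                n = 10 - (year % 10)
                chunk = vals[i : i + n]
                fh.write(f"{s.series_id:<8}{year:>6}" + "".join(f"{v:>6d}" for v in chunk) + "\n")
                i += len(chunk)
                year += len(chunk)


_REQUIRED_META = ["site_id", "species", "soil_class", "latitude", "longitude", "ice_region_id"]


def read_site_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar site-metadata table (CSV/TSV, sniffed separator)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _REQUIRED_META if c not in df.columns]
    if missing:
        raise ValueError(f"site metadata missing columns: {missing}")
    return df


def attach_metadata(series: Iterable[RingSeries], meta: pd.DataFrame) -> list[RingSeries]:
    """Return copies of ``series`` with sidecar metadata merged in by site_id."""
    rows = meta.set_index("site_id")
    out = []
    for s in series:
        if s.site_id in rows.index:
            r = rows.loc[s.site_id]
            out.append(
                replace(
                    s,
                    species=str(r["species"]),
                    soil_class=str(r["soil_class"]),
                    latitude=float(r["latitude"]),
                    longitude=float(r["longitude"]),
                    ice_region_id=str(r["ice_region_id"]),
                )
            )
        else:
            out.append(replace(s))
    return out


def series_stats(s: RingSeries) -> SeriesStats:
    """Mean sensitivity, lag-1 autocorrelation and span of one series.

    Zero widths (locally absent rings) stay in the series; consecutive
    pairs whose sum is zero are excluded from the MS mean.
    """
    w = s.widths
    if w.size < 2:
        raise ValueError(f"series {s.series_id!r}: need >= 2 rings for statistics")
    pair_sum = w[1:] + w[:-1]
    ok = pair_sum > 0
    if not np.any(ok):
        ms = math.nan
    else:
        ms = float(np.mean(np.abs(2.0 * (w[1:] - w[:-1])[ok] / pair_sum[ok])))
    if w.size < 3 or np.std(w[:-1]) == 0 or np.std(w[1:]) == 0:
        ar1 = math.nan
    else:
        ar1 = float(np.corrcoef(w[:-1], w[1:])[0, 1])
    return SeriesStats(n_rings=s.n_rings, ms=ms, ar1=ar1, span=(s.first_year, s.last_year))


@dataclass(frozen=True)
class ScreenResult:
    retained: list
    excluded: dict[str, str]  # chrono_id -> reason


def screen_chronologies(
    chronologies: Sequence,
    eps_min: float = 0.75,
    common_period: tuple[int, int] = (1979, 2008),
    manual_flags: Mapping[str, str] | None = None,
) -> ScreenResult:
    """Partition chronologies into retained and excluded-with-reason.

    A chronology is retained iff its EPS exceeds ``eps_min`` and its year
    span fully covers ``common_period``.  ``manual_flags`` records
    exclusions on grounds outside these two rules (e.g. sampling-design
    concerns); flagged chronologies are excluded with the given reason.
    """
    manual_flags = dict(manual_flags or {})
    retained: list = []
    excluded: dict[str, str] = {}
    lo, hi = common_period
    for c in chronologies:
        cid = c.chrono_id
        reasons = []
        if cid in manual_flags:
            reasons.append(manual_flags[cid])
        eps = c.eps
        if not (eps is not None and not math.isnan(eps) and eps > eps_min):
            reasons.append("EPS below threshold")
        first, last = int(c.years[0]), int(c.years[-1])
        if not (first <= lo and last >= hi):
            reasons.append("incomplete common period")
        if reasons:
            excluded[cid] = "; ".join(reasons)
        else:
            retained.append(c)
    return ScreenResult(retained=retained, excluded=excluded)
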