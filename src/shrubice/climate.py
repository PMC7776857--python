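"""Thornthwaite PET, climatic water balance, and the SPEI drought index.

Potential evapotranspiration follows Thornthwaite's temperature and
day-length formulation::

    PET_m = 16 * (L_m/12) * (N_m/30) * (10*T_m/I)**a     [mm/month]

with ``T_m`` the monthly mean temperature (PET = 0 for T_m <= 0), ``I``
the annual heat index ``sum((T_m/5)**1.514)`` over months above 0 C,
``a`` a cubic polynomial in I, ``L_m`` the mean day length (hours) from
latitude and month, and ``N_m`` the number of days in the month.  Day
length comes from the standard solar-declination formula evaluated at
the month's middle day, with the polar day/night argument clamped so
day length stays within [0, 24] h.

The water balance is ``D_m = P_m - PET_m``.  SPEI at scale k aggregates
D over a trailing k-month window, fits a three-parameter log-logistic
distribution per calendar month by unbiased probability-weighted
moments, and maps the fitted CDF through the standard-normal quantile
function, so each calendar month's SPEI is ~N(0, 1) over the
calibration period.
"""

from __future__ import annotations

import calendar
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "read_climate_table",
    "day_length_hours",
    "thornthwaite_pet",
    "water_balance",
    "spei",
    "SPEISeries",
    "jja_aggregate",
]

_MID_MONTH_DOY = np.array([15, 45, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349])
_DAYS_IN_MONTH = np.array([calendar.monthrange(2001, m)[1] for m in range(1, 13)], float)

_PROB_CLIP = 1e-8  # keeps the normal quantile finite at the sample extremes
_SPEI_BOUND = 3.09  # standard +-3.09 clamp (0.001 quantile convention):
# quantiles beyond the calibration sample's resolution are not meaningful


def read_climate_table(path: str | Path) -> pd.DataFrame:
    """Read monthly climate (site_id, year, month, tmean_c, precip_mm)."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"site_id", "year", "month", "tmean_c", "precip_mm"}
    if not need.issubset(df.columns):
        raise ValueError(f"climate table must have columns {sorted(need)}")
    if (df["precip_mm"] < 0).any():
        raise ValueError("negative precipitation")
    return df


def day_length_hours(latitude: float, month: int) -> float:
    """Mean day length (h) for a month at a latitude, clamped to [0, 24]."""
    doy = _MID_MONTH_DOY[month - 1]
    decl = 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)
    arg = -math.tan(math.radians(latitude)) * math.tan(decl)
    arg = min(1.0, max(-1.0, arg))  # polar day/night
    return 24.0 / math.pi * math.acos(arg)


def thornthwaite_pet(climate: pd.DataFrame, latitude: float) -> pd.Series:
    """Monthly Thornthwaite PET (mm) for one site.

    ``climate`` needs columns year, month, tmean_c with every year
    complete (12 months) so the annual heat index is defined.
    """
    df = climate[["year", "month", "tmean_c"]].copy()
    counts = df.groupby("year")["month"].nunique()
    bad = counts[counts < 12]
    if len(bad):
        raise ValueError(f"incomplete years for heat index: {list(bad.index)}")

    out = {}
    for year, grp in df.groupby("year"):
        t = grp.set_index("month")["tmean_c"]
        warm = t[t > 0]
        heat_index = float(((warm / 5.0) ** 1.514).sum())
        a = (
            6.75e-7 * heat_index**3
            - 7.71e-5 * heat_index**2
            + 1.792e-2 * heat_index
            + 0.49239
        )
        for m in range(1, 13):
            tm = float(t.loc[m])
            if tm <= 0 or heat_index <= 0:
                pet = 0.0
            else:
                lm = day_length_hours(latitude, m) / 12.0
                nm = _DAYS_IN_MONTH[m - 1] / 30.0
                pet = 16.0 * lm * nm * (10.0 * tm / heat_index) ** a
            out[(int(year), m)] = pet
    ser = pd.Series(out, name="pet_mm")
    ser.index = pd.MultiIndex.from_tuples(ser.index, names=["year", "month"])
    return ser.sort_index()


def water_balance(climate: pd.DataFrame, pet: pd.Series) -> pd.Series:
    """Monthly climatic water balance D = P - PET (mm)."""
    p = climate.set_index(["year", "month"])["precip_mm"].sort_index()
    if not p.index.equals(pet.index):
        raise ValueError("precipitation and PET coverage do not match")
    d = p - pet
    d.name = "d_mm"
    return d


@dataclass
class SPEISeries:
    """SPEI values with the fitted per-calendar-month distributions."""

    scale_k: int
    values: pd.DataFrame  # index (year, month); columns d_agg, spei
    params: dict[int, tuple[float, float, float]]  # month -> (xi, alpha, kappa)


def _pwm_loglogistic(x: np.ndarray) -> tuple[float, float, float]:
    """Fit the 3-parameter log-logistic by unbiased PWMs / L-moments.

    Uses the generalized-logistic parameterization (location xi, scale
    alpha, shape kappa = -tau3), which coincides with the classical
    log-logistic for right-skewed samples and remains valid on the
    reflected (left-skewed) branch.  Returns (xi, alpha, kappa).
    """
    x = np.sort(np.asarray(x, float))
    n = x.size
    if n < 4:
        raise ValueError("need >= 4 values for the log-logistic fit")
    i = np.arange(1, n + 1)
    # unbiased PWMs b_s = E[F^s X] -> L-moments
    b0 = x.mean()
    b1 = np.sum((i - 1) / (n - 1) * x) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * x) / n
    l1 = b0
    l2 = 2.0 * b1 - b0
    l3 = 6.0 * b2 - 6.0 * b1 + b0
    if l2 <= 0:
        raise ValueError("degenerate sample for log-logistic fit (l2 <= 0)")
    tau3 = l3 / l2
    kappa = -tau3
    if abs(kappa) >= 0.999:
        raise ValueError(f"log-logistic shape out of range (tau3={tau3:.3g})")
    if abs(kappa) < 1e-8:
        alpha = l2
        xi = l1
        return float(xi), float(alpha), 0.0
    g = kappa * math.pi / math.sin(kappa * math.pi)
    alpha = l2 / g
    xi = l1 - alpha * (1.0 / kappa - math.pi / math.sin(kappa * math.pi))
    return float(xi), float(alpha), float(kappa)


def _loglogistic_cdf(x: np.ndarray, xi: float, alpha: float, kappa: float) -> np.ndarray:
    z = (np.asarray(x, float) - xi) / alpha
    if kappa == 0.0:
        y = z
    else:
        arg = 1.0 - kappa * z
        y = np.where(arg > 0, -np.log(np.maximum(arg, 1e-300)) / kappa, 0.0)
        # beyond the finite bound: lower bound (kappa < 0) -> F=0, upper -> F=1
        y = np.where(arg > 0, y, math.inf if kappa > 0 else -math.inf)
    return 1.0 / (1.0 + np.exp(-y))


def spei(
    d: pd.Series,
    scale_k: int = 12,
    calibration_period: tuple[int, int] | None = None,
    min_years: int = 20,
) -> SPEISeries:
    """SPEI of a monthly water-balance series at a k-month timescale.

    D is summed over the trailing k months (the first k-1 months are
    dropped); each calendar month's aggregates are fitted separately on
    the calibration years (default: all years) and transformed through
    the fitted log-logistic CDF and the standard-normal quantile.
    """
    d = d.sort_index()
    if scale_k < 1:
        raise ValueError("scale_k must be >= 1")
    if scale_k > len(d):
        raise ValueError(f"scale {scale_k} exceeds series length {len(d)}")
    agg = d.rolling(scale_k).sum().iloc[scale_k - 1 :]

    frame = agg.rename("d_agg").reset_index()
    params: dict[int, tuple[float, float, float]] = {}
    spei_vals = pd.Series(index=agg.index, dtype=float)
    for m, grp in frame.groupby("month"):
        vals = grp.set_index("year")["d_agg"]
        calib = vals.loc[calibration_period[0] : calibration_period[1]] if calibration_period else vals
        if len(calib) < min_years:
            raise ValueError(f"calendar month {m}: only {len(calib)} calibration years (< {min_years})")
        if float(calib.std()) == 0:
            raise ValueError(f"calendar month {m}: constant water balance")
        try:
            xi, alpha, kappa = _pwm_loglogistic(calib.to_numpy())
        except ValueError as e:
            raise ValueError(f"calendar month {m}: {e}") from None
        params[int(m)] = (xi, alpha, kappa)
        prob = _loglogistic_cdf(vals.to_numpy(), xi, alpha, kappa)
        prob = np.clip(prob, _PROB_CLIP, 1.0 - _PROB_CLIP)
        idx = pd.MultiIndex.from_arrays([vals.index, np.full(len(vals), m)], names=["year", "month"])
        spei_vals.loc[idx] = np.clip(ndtri(prob), -_SPEI_BOUND, _SPEI_BOUND)

    out = pd.DataFrame({"d_agg": agg, "spei": spei_vals})
    return SPEISeries(scale_k=scale_k, values=out.sort_index(), params=params)


def jja_aggregate(x: pd.Series) -> pd.Series:
    """Per-year June-August mean of a monthly series indexed by (year, month).

    Years missing any of the three months are omitted.
    """
    df = x.reset_index()
    df.columns = ["year", "month", "value"]
    summer = df[df["month"].isin([6, 7, 8])]
    counts = summer.groupby("year")["month"].nunique()
    full = counts[counts == 3].index
    out = summer[summer["year"].isin(full)].groupby("year")["value"].mean()
    out.name = getattr(x, "name", None) or "jja"
    return out
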