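"""Diameter regional-curve standardization (dRCS) and chronology building.

Ring widths are standardized against an empirical curve of expected ring
width versus stem *radius at the time the ring formed* (rather than
cambial age).  Dividing observed by expected width yields dimensionless
ring-width indices (RWI); the arithmetic mean of member indices per year
is the site chronology.  Optionally the standardization runs in
signal-free mode: the common year-signal (the current chronology) is
divided out of the measurements before the curve is refitted, which
reduces trend distortion when the common signal itself carries a trend.

Chronology quality is summarised by rbar (mean pairwise correlation of
member series) and the expressed population signal
``EPS = n·rbar / (n·rbar + 1 - rbar)`` with ``n`` the mean sample depth.

``ar_prewhiten`` provides the "double detrending" step used for
high-frequency analyses: residuals of an AR(p) model (order chosen by
AIC), with the series mean added back, scaled to mean one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ringio import RingSeries

__all__ = [
    "RegionalCurve",
    "RWISeries",
    "Chronology",
    "cumulative_radius",
    "fit_regional_curve",
    "drcs_standardize",
    "build_chronology",
    "ar_prewhiten",
]


def cumulative_radius(s: RingSeries) -> np.ndarray:
    """Stem radius (mm) at the start of each year's ring formation.

    The radius in year t is the sum of all widths laid down before t, so
    the first ring forms at radius 0.
    """
    w = s.widths
    return np.concatenate(([0.0], np.cumsum(w)[:-1]))


@dataclass(frozen=True)
class RegionalCurve:
    """Expected ring width (mm) as a function of stem radius (mm).

    Piecewise-linear interpolation between knots; evaluation outside the
    support clamps to the nearest knot value.  ``floor`` is the minimum
    expected width enforced at fit time.
    """

    knot_radius: np.ndarray
    knot_width: np.ndarray
    method: str = "binned_mean"
    floor: float = 0.0

    def __post_init__(self) -> None:
        kr = np.asarray(self.knot_radius, float)
        kw = np.asarray(self.knot_width, float)
        object.__setattr__(self, "knot_radius", kr)
        object.__setattr__(self, "knot_width", kw)
        if kr.size != kw.size or kr.size < 1:
            raise ValueError("curve needs matching, non-empty knot arrays")
        if np.any(np.diff(kr) <= 0):
            raise ValueError("knot radii must be strictly increasing")
        if np.any(kw <= 0):
            raise ValueError("expected widths must be positive")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.knot_radius[0]), float(self.knot_radius[-1])

    def __call__(self, radius: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(radius, float), self.knot_radius, self.knot_width)

    def scaled(self, c: float) -> "RegionalCurve":
        """The curve under a change of measurement scale: w(r) -> c*w(r/c)."""
        return RegionalCurve(self.knot_radius * c, self.knot_width * c, self.method, self.floor * c)


def fit_regional_curve(
    series: Sequence[RingSeries],
    method: str = "binned_mean",
    bin_width: float = 1.0,
    spline_smoothing: float | None = None,
    floor_frac: float = 0.05,
    _widths_override: Sequence[np.ndarray] | None = None,
) -> RegionalCurve:
    """Fit the regional curve to pooled (radius, width) pairs.

    ``binned_mean`` (default) averages widths in radius bins of
    ``bin_width`` mm and interpolates linearly between bin centres;
    ``spline_on_radius`` additionally smooths the binned means with a
    cubic smoothing spline.  Expected widths are floored at
    ``floor_frac`` times the pooled mean width so indices cannot blow up
    at sparse support edges.
    """
    if len(series) < 1:
        raise ValueError("need at least one series")
    radii, widths = [], []
    for i, s in enumerate(series):
        r = cumulative_radius(s)
        w = s.widths if _widths_override is None else np.asarray(_widths_override[i], float)
        radii.append(r)
        widths.append(w)
    radius = np.concatenate(radii)
    width = np.concatenate(widths)
    if radius.size < 10:
        raise ValueError(f"need >= 10 pooled (radius, width) pairs, got {radius.size}")

    edges = np.arange(0.0, radius.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(radius, edges) - 1, 0, edges.size - 2)
    sums = np.bincount(idx, weights=width, minlength=edges.size - 1)
    counts = np.bincount(idx, minlength=edges.size - 1)
    nonempty = counts > 0
    centers = (edges[:-1] + edges[1:]) / 2.0
    kr = centers[nonempty]
    kw = sums[nonempty] / counts[nonempty]

    if method == "spline_on_radius":
        from scipy.interpolate import UnivariateSpline

        if kr.size >= 4:
            s_val = spline_smoothing if spline_smoothing is not None else kr.size * np.var(kw) * 0.1
            spl = UnivariateSpline(kr, kw, k=3, s=s_val)
            kw = spl(kr)
    elif method != "binned_mean":
        raise ValueError(f"unknown curve method {method!r}")

    floor = floor_frac * float(width.mean())
    if floor <= 0:
        raise ValueError("pooled mean width must be positive")
    kw = np.maximum(kw, floor)
    if kr.size == 1:  # all rings in one bin: flat curve
        kr = np.array([kr[0] - 0.5 * bin_width, kr[0] + 0.5 * bin_width])
        kw = np.array([kw[0], kw[0]])
    return RegionalCurve(kr, kw, method=method, floor=floor)


@dataclass
class RWISeries:
    """Dimensionless ring-width indices for one series."""

    series_id: str
    years: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.indices = np.asarray(self.indices, float)
        if self.years.size != self.indices.size:
            raise ValueError("years and indices must align")


@dataclass
class Chronology:
    """Site-by-species mean ring-width index with quality statistics."""

    chrono_id: str
    years: np.ndarray
    rwi: np.ndarray
    depth: np.ndarray
    eps: float = math.nan
    rbar_tot: float = math.nan
    signal_free: bool = False
    n_iterations: int = 0

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.rwi = np.asarray(self.rwi, float)
        self.depth = np.asarray(self.depth, int)

    def as_series(self) -> pd.Series:
        return pd.Series(self.rwi, index=pd.Index(self.years, name="year"), name=self.chrono_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "rwi": self.rwi, "depth": self.depth})


def _mean_chronology(rwis: Sequence[RWISeries]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y0 = min(int(r.years[0]) for r in rwis)
    y1 = max(int(r.years[-1]) for r in rwis)
    years = np.arange(y0, y1 + 1)
    total = np.zeros(years.size)
    depth = np.zeros(years.size, int)
    for r in rwis:
        i = r.years - y0
        total[i] += r.indices
        depth[i] += 1
    has = depth > 0
    mean = np.full(years.size, np.nan)
    mean[has] = total[has] / depth[has]
    return years[has], mean[has], depth[has]


def eps_from_rbar(rbar: float, mean_depth: float) -> float:
    """Expressed population signal from mean pairwise r and mean depth.

    Undefined (NaN) when the common signal is absent (rbar <= 0).
    """
    denom = mean_depth * rbar + (1.0 - rbar)
    if rbar <= 0 or denom <= 0:
        return math.nan
    return (mean_depth * rbar) / denom


def build_chronology(
    rwis: Sequence[RWISeries],
    chrono_id: str,
    min_overlap: int = 10,
    signal_free: bool = False,
    n_iterations: int = 0,
) -> Chronology:
    """Arithmetic-mean chronology with rbar and EPS.

    rbar_tot is the mean pairwise Pearson correlation over series pairs
    sharing at least ``min_overlap`` years; EPS follows from rbar and the
    mean sample depth over the reported span.  With fewer than two
    usable pairs the statistics are NaN but the chronology is still
    returned.
    """
    if not rwis:
        raise ValueError("no RWI series supplied")
    years, rwi, depth = _mean_chronology(rwis)

    cors = []
    for i in range(len(rwis)):
        for j in range(i + 1, len(rwis)):
            a, b = rwis[i], rwis[j]
            common, ia, ib = np.intersect1d(a.years, b.years, return_indices=True)
            if common.size < min_overlap:
                continue
            x, y = a.indices[ia], b.indices[ib]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            cors.append(float(np.corrcoef(x, y)[0, 1]))
    if cors:
        rbar = float(np.mean(cors))
        eps = eps_from_rbar(rbar, float(depth.mean()))
    else:
        rbar = math.nan
        eps = math.nan
    return Chronology(
        chrono_id=chrono_id,
        years=years,
        rwi=rwi,
        depth=depth,
        eps=eps,
        rbar_tot=rbar,
        signal_free=signal_free,
        n_iterations=n_iterations,
    )


@dataclass
class DrcsResult:
    rwis: list[RWISeries]
    chronology: Chronology
    curve: RegionalCurve
    n_iterations: int
    converged: bool


def drcs_standardize(
    series: Sequence[RingSeries],
    curve: RegionalCurve | None = None,
    signal_free: bool = False,
    tol: float = 1e-4,
    max_iter: int = 100,
    refit_curve: bool = True,
    chrono_id: str = "chronology",
    **curve_kwargs,
) -> DrcsResult:
    """Standardize series to RWI by the diameter regional curve.

    ``index_t = width_t / expected_width(radius_t)``.  In signal-free
    mode the current chronology value for each year is divided out of
    the measurements, the curve is refitted (unless ``refit_curve`` is
    False), and indices are recomputed, until the largest year-wise
    chronology change falls below ``tol`` or ``max_iter`` is reached.
    Radii are always taken from the observed widths.
    """
    if not series:
        raise ValueError("no series supplied")
    radii = [cumulative_radius(s) for s in series]

    if curve is None:
        curve = fit_regional_curve(series, **curve_kwargs)

    def indices_for(c: RegionalCurve) -> list[RWISeries]:
        out = []
        for s, r in zip(series, radii):
            exp = c(r)
            if np.any(exp <= 0):
                raise ValueError(f"series {s.series_id!r}: expected width <= 0 on support")
            out.append(RWISeries(s.series_id, s.years, s.widths / exp))
        return out

    rwis = indices_for(curve)
    chron = build_chronology(rwis, chrono_id)
    n_iter = 0
    converged = True

    if signal_free:
        converged = False
        for n_iter in range(1, max_iter + 1):
            # rescale the common signal to mean 1 before dividing it out,
            # so the overall measurement scale is preserved across passes
            mu = float(chron.rwi.mean())
            chron_map = {int(y): v / mu for y, v in zip(chron.years, chron.rwi)}
            sf_widths = []
            for s in series:
                scale = np.array([chron_map.get(int(y), 1.0) for y in s.years])
                scale = np.where(scale > 0, scale, 1.0)
                sf_widths.append(s.widths / scale)
            if refit_curve:
                curve = fit_regional_curve(series, _widths_override=sf_widths, **curve_kwargs)
            rwis = indices_for(curve)
            new_chron = build_chronology(rwis, chrono_id)
            common, ia, ib = np.intersect1d(chron.years, new_chron.years, return_indices=True)
            delta = float(np.max(np.abs(chron.rwi[ia] - new_chron.rwi[ib]))) if common.size else 0.0
            chron = new_chron
            if delta < tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"signal-free iteration did not converge in {max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )

    chron.signal_free = signal_free
    chron.n_iterations = n_iter
    return DrcsResult(rwis=rwis, chronology=chron, curve=curve, n_iterations=n_iter, converged=converged)


def _levinson_durbin(acf: np.ndarray, p_max: int) -> list[tuple[np.ndarray, float]]:
    """Yule-Walker solutions (phi, prediction variance) for orders 0..p_max."""
    out = [(np.empty(0), float(acf[0]))]
    phi = np.zeros(p_max + 1)
    v = float(acf[0])
    phi_prev = np.zeros(p_max + 1)
    for k in range(1, p_max + 1):
        acc = acf[k] - np.dot(phi_prev[1:k], acf[1:k][::-1])
        ref = acc / v
        phi[k] = ref
        phi[1:k] = phi_prev[1:k] - ref * phi_prev[1:k][::-1]
        v = v * (1.0 - ref * ref)
        phi_prev[: k + 1] = phi[: k + 1]
        out.append((phi[1 : k + 1].copy(), v))
    return out


def ar_prewhiten(x: np.ndarray, p_max: int = 5) -> tuple[np.ndarray, int]:
    """AR-prewhiten an annual series; returns (series with mean 1, order).

    The AR order p in 0..p_max is selected by AIC on Yule-Walker fits
    (``n·log(v_p) + 2p`` with v_p the prediction variance).  The output
    is the AR residuals with the series mean added back, divided by
    their mean, so the result is white-noise-like with mean exactly 1.
    The first p values are dropped.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for AR prewhitening (need >= 10)")
    if np.std(x) == 0:
        raise ValueError("constant series cannot be prewhitened")
    m = x.mean()
    xc = x - m
    p_max = min(p_max, n - 2)
    acf = np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(p_max + 1)])
    fits = _levinson_durbin(acf, p_max)
    aic = [n * math.log(max(v, 1e-300)) + 2 * p for p, (_, v) in enumerate(fits)]
    order = int(np.argmin(aic))
    phi, _ = fits[order]
    if order == 0:
        resid = xc.copy()
    else:
        resid = np.array(
            [xc[t] - np.dot(phi, xc[t - order : t][::-1]) for t in range(order, n)]
        )
    resid_full = resid + m
    rm = resid_full.mean()
    if rm == 0:
        raise ValueError("prewhitened residual mean is zero; cannot scale to mean 1")
    return resid_full / rm, order
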