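"""Chronology-to-sea-ice linkage statistics.

The screening step correlates each shrub chronology with a battery of
sea-ice variables (monthly previous-June through current-August plus
seasonal aggregates, Pan-Arctic and regional), adjusts p-values within
each chronology row by Benjamini-Hochberg, and classifies chronologies
into responder groups: *increasers* (significantly negative correlation
with at least one sea-ice extent variable, i.e. growth rises as ice
declines), *decreasers* (significantly positive), *neutral* (nothing
significant) and *ambiguous* (both signs significant).  k-means on the
monthly correlation profiles corroborates the sign-based grouping.

Temporal stability of the association is probed with 20-year moving
windows whose Pearson correlations get pairs-bootstrap percentile
intervals, and with Welch two-sample contrasts between an early and a
recent epoch; group trend differences are tested through a slope
interaction model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationScreen",
    "ResponderAssignment",
    "MovingCorrelationResult",
    "correlation_screen",
    "classify_responders",
    "kmeans_responders",
    "moving_bootstrap_correlation",
    "epoch_contrast",
    "compare_slopes",
    "benjamini_hochberg",
]


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(p, float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationScreen:
    """Pearson r / p / row-wise BH-adjusted p per (chronology, variable)."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame

    def row(self, chrono_id: str) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r.loc[chrono_id], "p": self.p.loc[chrono_id], "p_adj": self.p_adj.loc[chrono_id]}
        )

    def to_long(self) -> pd.DataFrame:
        out = []
        for cid in self.r.index:
            row = self.row(cid).reset_index(names="variable")
            row.insert(0, "chrono_id", cid)
            out.append(row)
        return pd.concat(out, ignore_index=True)


def correlation_screen(
    chronologies: Mapping[str, pd.Series],
    ice_variables: Mapping[str, pd.Series],
    period: tuple[int, int] | None = None,
    min_overlap: int = 10,
) -> CorrelationScreen:
    """Screen chronologies against sea-ice variables over a year period.

    Each series is indexed by year.  Cells with fewer than
    ``min_overlap`` overlapping years are NaN.  BH adjustment runs
    within each chronology's row over its non-missing cells.
    """
    cids = list(chronologies)
    vids = list(ice_variables)
    r = pd.DataFrame(np.nan, index=cids, columns=vids)
    p = pd.DataFrame(np.nan, index=cids, columns=vids)
    for cid in cids:
        c = chronologies[cid].dropna()
        if period:
            c = c.loc[period[0] : period[1]]
        for vid in vids:
            v = ice_variables[vid].dropna()
            if period:
                v = v.loc[period[0] : period[1]]
            common = c.index.intersection(v.index)
            if len(common) < min_overlap:
                continue
            x, y = c.loc[common].to_numpy(), v.loc[common].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r.loc[cid, vid] = res.statistic
            p.loc[cid, vid] = res.pvalue
    p_adj = p.copy()
    for cid in cids:
        ok = p.loc[cid].notna()
        if ok.any():
            p_adj.loc[cid, ok] = benjamini_hochberg(p.loc[cid, ok].to_numpy())
    return CorrelationScreen(r=r, p=p, p_adj=p_adj)


@dataclass
class ResponderAssignment:
    chrono_id: str
    label: str  # increaser | decreaser | neutral | ambiguous
    evidence: list = field(default_factory=list)  # (variable, r, p)


def classify_responders(
    screen: CorrelationScreen,
    alpha: float = 0.05,
    use_fdr: bool = False,
) -> list[ResponderAssignment]:
    """Label each chronology by the sign of its significant correlations.

    Significance uses raw p < alpha by default (set ``use_fdr`` to use
    the BH-adjusted values instead).  At least one significant negative
    and none positive -> increaser; the symmetric case -> decreaser;
    nothing significant -> neutral; both signs -> ambiguous.
    """
    pmat = screen.p_adj if use_fdr else screen.p
    out = []
    for cid in screen.r.index:
        sig = pmat.loc[cid] < alpha
        ev_neg = [
            (v, float(screen.r.loc[cid, v]), float(pmat.loc[cid, v]))
            for v in screen.r.columns
            if bool(sig[v]) and screen.r.loc[cid, v] < 0
        ]
        ev_pos = [
            (v, float(screen.r.loc[cid, v]), float(pmat.loc[cid, v]))
            for v in screen.r.columns
            if bool(sig[v]) and screen.r.loc[cid, v] > 0
        ]
        if ev_neg and not ev_pos:
            label = "increaser"
        elif ev_pos and not ev_neg:
            label = "decreaser"
        elif not ev_neg and not ev_pos:
            label = "neutral"
        else:
            label = "ambiguous"
        out.append(ResponderAssignment(cid, label, ev_neg + ev_pos))
    return out


def kmeans_responders(
    profiles: pd.DataFrame,
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    n_init: int = 10,
    seed: int = 0,
) -> dict:
    """k-means over per-chronology correlation profiles.

    ``profiles`` has one row per chronology (e.g. its correlations with
    the monthly Pan-Arctic variables).  Returns labels and within-group
    sum of squares per k, with the elbow k chosen by the largest
    second difference of the WSS curve (k=min(k_range) if the curve is
    flat).
    """
    X = profiles.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("correlation profiles contain missing cells")
    ks = sorted(k_range)
    if ks[-1] > X.shape[0]:
        raise ValueError(f"k={ks[-1]} exceeds {X.shape[0]} rows")
    wss: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
        wss[k] = float(km.inertia_)
        labels[k] = km.labels_
    if len(ks) >= 3:
        interior = ks[1:-1]
        curv = {k: (wss[k - 1] - wss[k]) - (wss[k] - wss[k + 1]) for k in interior if k - 1 in wss and k + 1 in wss}
        k_best = max(curv, key=curv.get) if curv else ks[0]
    else:
        k_best = ks[0]
    return {"wss": wss, "labels": labels, "k_best": int(k_best)}


@dataclass
class MovingCorrelationResult:
    window_length: int
    window_starts: np.ndarray  # first year of each window
    r: np.ndarray
    significant: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r for equal-shape 2-d arrays."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def moving_bootstrap_correlation(
    chronology: pd.Series,
    variable: pd.Series,
    window: int = 20,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> MovingCorrelationResult:
    """Moving-window Pearson correlation with pairs-bootstrap intervals.

    Windows of ``window`` years slide by one year over the common span.
    A window is flagged significant when its percentile bootstrap
    interval at level 1-alpha (case resampling of year pairs) excludes
    zero.
    """
    common = chronology.dropna().index.intersection(variable.dropna().index)
    x = chronology.loc[common].to_numpy(float)
    y = variable.loc[common].to_numpy(float)
    years = np.asarray(common, int)
    n = x.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    rng = np.random.default_rng(seed)
    n_win = n - window + 1
    r = np.empty(n_win)
    sig = np.zeros(n_win, bool)
    lo = np.empty(n_win)
    hi = np.empty(n_win)
    for w in range(n_win):
        xs, ys = x[w : w + window], y[w : w + window]
        r[w] = float(np.corrcoef(xs, ys)[0, 1])
        idx = rng.integers(0, window, size=(n_boot, window))
        rb = _pearson_rows(xs[idx], ys[idx])
        rb = rb[np.isfinite(rb)]
        lo[w], hi[w] = np.percentile(rb, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        sig[w] = (lo[w] > 0) or (hi[w] < 0)
    return MovingCorrelationResult(
        window_length=window,
        window_starts=years[:n_win],
        r=r,
        significant=sig,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
    )


@dataclass(frozen=True)
class EpochContrast:
    mean_early: float
    mean_recent: float
    t: float
    df: float
    p: float


def epoch_contrast(
    x: pd.Series,
    early: tuple[int, int] = (1979, 1993),
    recent: tuple[int, int] = (1994, 2008),
) -> EpochContrast:
    """Welch two-sample contrast of annual values between two epochs."""
    a = x.loc[early[0] : early[1]].dropna().to_numpy(float)
    b = x.loc[recent[0] : recent[1]].dropna().to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each epoch needs at least 2 values")
    res = stats.ttest_ind(b, a, equal_var=False)
    return EpochContrast(
        mean_early=float(a.mean()),
        mean_recent=float(b.mean()),
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
    )


def compare_slopes(groups: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> dict:
    """Per-group OLS slopes plus an interaction test for slope equality.

    ``groups`` maps label -> (x, y).  The pooled model
    ``y ~ x * group`` provides the slope-difference test: with two
    groups the interaction t-test p, in general the F-test over all
    interaction terms.
    """
    import statsmodels.formula.api as smf

    if len(groups) < 2:
        raise ValueError("need at least two groups")
    frames = []
    slopes = {}
    for g, (x, y) in groups.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.size < 3:
            raise ValueError(f"group {g!r}: need >= 3 points")
        if np.std(x) == 0:
            raise ValueError(f"group {g!r}: singular design (constant x)")
        b, a = np.polyfit(x, y, 1)
        slopes[g] = float(b)
        frames.append(pd.DataFrame({"x": x, "y": y, "group": g}))
    df = pd.concat(frames, ignore_index=True)
    fit = smf.ols("y ~ x * C(group)", data=df).fit()
    inter = [t for t in fit.params.index if ":" in t]
    ftest = fit.f_test([f"{t} = 0" for t in inter])
    labels = sorted(groups)
    return {
        "slopes": slopes,
        "slope_difference": slopes[labels[1]] - slopes[labels[0]] if len(labels) == 2 else math.nan,
        "interaction_p": float(ftest.pvalue),
        "model": fit,
    }
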