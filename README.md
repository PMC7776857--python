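# shrubice

Analysis pipeline linking Arctic **shrub radial growth** to **sea-ice
decline**. It is aimed at dendroecologists and ecological climatologists who
work with cross-dated shrub ring-width series (*Betula*, *Salix*) and want to
relate site chronologies to sea-ice extent, sea-ice phenology and summer
climate — and at methodologists who want every stage of such a synthesis
testable against synthetic data with known ground truth.

## What it computes

The pipeline runs the stages of a pan-Arctic shrub-ring / sea-ice synthesis:

1. **Ring-width I/O and screening** (`shrubice.ringio`) — Tucson/RWL decadal
   format (both 0.01 mm / `999` and 0.001 mm / `-9999` dialects), per-series
   mean sensitivity and lag-1 autocorrelation, and chronology screening by
   expressed population signal (EPS > 0.75) and common-period coverage
   (1979–2008).
2. **Diameter regional-curve standardization** (`shrubice.detrend`) — the
   expected ring width is modelled as a function of stem radius at ring
   formation; the ring-width index is `RWI_t = w_t / f(r_t)`, with the curve
   `f` fitted to the pooled population and optionally iterated *signal-free*
   (the common year-signal is divided out of the measurements before each
   refit). Chronology quality uses
   `EPS = n·r̄ / (n·r̄ + 1 − r̄)` with `r̄` the mean pairwise correlation
   between member series and `n` the mean sample depth. AR prewhitening
   (order by AIC) supports high-frequency "double-detrended" analyses.
3. **Sea ice** (`shrubice.seaice`) — monthly extent series with adjacent-year
   gap filling, seasonal aggregates with previous-year alignment (`pSON`,
   `pDJF`, …), and retreat/advance phenology from daily concentration grids:
   per cell the last day concentration drops below a threshold (default 50 %
   SIC) before the minimum-extent day (LRD) and the first day it returns
   above it (FAD), area-weighted over cells that experience both crossings.
4. **Climate** (`shrubice.climate`) — Thornthwaite potential
   evapotranspiration `PET_m = 16 (L_m/12)(N_m/30)(10 T_m/I)^a`, climatic
   water balance `D = P − PET`, and SPEI: `D` summed over a trailing
   k-month window, fitted per calendar month with a three-parameter
   log-logistic distribution by unbiased probability-weighted moments, and
   mapped through the standard-normal quantile.
5. **Linkage statistics** (`shrubice.linkage`) — Pearson screening of
   chronologies against monthly (previous June → current August) and
   seasonal sea-ice variables with Benjamini–Hochberg adjustment per
   chronology; responder classification (*increasers* correlate negatively
   with ice extent, *decreasers* positively, *neutral* neither); k-means
   corroboration on correlation profiles; 20-year moving-window correlations
   with 1000-fold pairs-bootstrap intervals; Welch epoch contrasts
   (1979–1993 vs 1994–2008); slope-interaction comparisons.
6. **Piecewise SEM** (`shrubice.sem`) — per-node linear mixed models
   (random site intercept, AR(1) residuals, exact maximum likelihood) over a
   directed path diagram `ice → temp/precip/SPEI → RWI`; Shipley's
   d-separation test with Fisher's `C = −2 Σ ln p_i ~ χ²(2k)`; marginal and
   conditional R²; AICc and Akaike-weight model ranking.
7. **Synthetic study generator** (`shrubice.synthdata`) — declining, noisy
   sea ice; coupled monthly climate; shrub populations grown on a
   diameter-dependent curve times a climate-driven signal with known path
   coefficients and "increaser"/"decreaser" site structure.

## Worked example

Simulate a small three-site study, build signal-free dRCS chronologies, and
screen them against pan-Arctic sea-ice extent:

```python
from shrubice import synthdata, detrend, seaice, linkage

study = synthdata.simulate_system(
    synthdata.SimulationConfig(seed=42, n_increaser_sites=2, n_decreaser_sites=1)
)

groups = {}
for s in study.series:
    groups.setdefault(s.site_id, []).append(s)
chronos = {}
for sid, grp in sorted(groups.items()):
    res = detrend.drcs_standardize(grp, signal_free=True, chrono_id=sid)
    c = res.chronology
    chronos[sid] = c
    print(f"{sid}: {len(grp)} shrubs, {c.years[0]}-{c.years[-1]}, "
          f"EPS={c.eps:.3f}, rbar={c.rbar_tot:.3f}, {res.n_iterations} iterations")

ice = seaice.fill_monthly_gaps(study.ice["panarctic"])
ice_vars = {f"pM{m:02d}": seaice.monthly_variable(ice, m, previous=True) for m in range(6, 13)}
ice_vars |= {f"M{m:02d}": seaice.monthly_variable(ice, m) for m in range(1, 9)}
ice_vars |= {s: seaice.seasonal_aggregate(ice, s) for s in ("JJA", "pSON")}

screen = linkage.correlation_screen(
    {sid: c.as_series() for sid, c in chronos.items()}, ice_vars, period=(1979, 2008)
)
for r in linkage.classify_responders(screen):
    row = screen.row(r.chrono_id)
    strongest = row["r"].abs().idxmax()
    print(f"{r.chrono_id}: {r.label:9s} strongest {strongest} "
          f"r={row.loc[strongest, 'r']:+.2f} (p={row.loc[strongest, 'p']:.1e}), "
          f"{len(r.evidence)}/{len(ice_vars)} variables significant")
```

Output:

```
DEC01: 30 shrubs, 1952-2008, EPS=0.955, rbar=0.469, 13 iterations
INC01: 30 shrubs, 1952-2008, EPS=0.949, rbar=0.463, 15 iterations
INC02: 30 shrubs, 1952-2008, EPS=0.956, rbar=0.484, 21 iterations
DEC01: decreaser strongest M01 r=+0.83 (p=1.7e-08), 17/17 variables significant
INC01: increaser strongest M03 r=-0.81 (p=4.3e-08), 17/17 variables significant
INC02: increaser strongest M04 r=-0.49 (p=5.7e-03), 16/17 variables significant
```

All three chronologies pass the EPS screen; the two sites forced through the
temperature pathway correlate negatively with sea-ice extent (increasers:
growth rises as ice declines) and the moisture-forced site positively
(decreaser: growth falls as ice declines, via drying).

A full configuration-driven run (detrending → screening → phenology → SPEI →
linkage → SEM, all output tables written with a config hash) is available
from the command line:

```sh
shrubice simulate --preset tiny --seed 2 --out study/
shrubice run-all --config config.yml --out results/
```

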