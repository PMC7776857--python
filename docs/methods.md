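# Methods

This note documents the models implemented in `shrubice`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user auditing results should know
about. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Ring-width data and screening

Input series are cross-dated annual ring widths (mm) in Tucson/RWL decadal
format. Both common dialects are read and auto-detected per series from the
stop marker: `999` (units 0.01 mm) and `-9999` (units 0.001 mm). Zero widths
encode locally absent rings; they stay in the series, and consecutive pairs
whose sum is zero are excluded from the mean-sensitivity denominator.

Mean sensitivity is `mean |2(w_{t+1} − w_t) / (w_{t+1} + w_t)|`; the lag-1
autocorrelation is the Pearson correlation of `(w_t, w_{t+1})` and is
flagged undefined (NaN) for constant series. A chronology enters the
analysis when its EPS exceeds **0.75** and its span covers the common period
**1979–2008** entirely; exclusions on other grounds (e.g. sampling-design
concerns) are supplied as explicit manual flags, never inferred.

Site metadata (species, soil class, coordinates, sea-ice region assignment)
travels in a sidecar delimited table keyed by `site_id`, since RWL has no
metadata fields. When a collection contains multiple cross-sections per
shrub, only sections flagged as root-collar enter chronology building.

## Diameter regional-curve standardization (dRCS)

The detrending curve is the empirical relation between ring width and the
stem **radius at the time the ring formed** (the prefix sum of earlier
widths), rather than cambial age. Aligning by radius rather than age
accommodates fast and slow growers with a single curve, which matters for
shrub datasets too small for multiple-curve approaches.

* Curve estimator: radius-binned means (bin width **1 mm**) joined by linear
  interpolation, clamped to the nearest knot outside the support; a cubic
  smoothing-spline variant is available. Binned means are parameter-light
  and reproducible.
* Expected widths are floored at **5 %** of the pooled mean width so indices
  cannot blow up at sparse support edges.
* `RWI_t = w_t / f(r_t)`; the site chronology is the arithmetic mean of
  member indices per year, reported only where depth ≥ 1 (no infilling).

**Signal-free iteration.** The common year-signal (current chronology,
rescaled to mean 1) is divided out of the measurements, the curve is
refitted (a switch disables refitting), and indices are recomputed, until
the largest year-wise chronology change is below **1e-4** or **100**
iterations are reached. The mean-1 rescaling removes a slow mean-drift mode
of the alternating update; the remaining contraction ratio on realistic
populations is ~0.93, hence the 100-iteration cap (each pass costs
milliseconds). Non-convergence returns the last iterate with a warning.
Radii are always computed from observed widths, not signal-free ones.

Identifiability caveat: when all members of a population germinate in the
same year, radius and calendar year are collinear and the curve can absorb
the common signal — no RCS variant can separate them. Recovery of a known
signal (tested at depth 30, 50 years, r > 0.95) requires staggered
germination, which real shrub populations and the generator both have.

**Chronology statistics.** `rbar_tot` is the mean pairwise Pearson
correlation over member pairs sharing ≥ 10 years;
`EPS = n̄·r̄ / (n̄·r̄ + 1 − r̄)` uses the mean sample depth over the
reported span (a single-number EPS; per-year EPS is out of scope). EPS is
reported as undefined when `r̄ ≤ 0`.

**AR prewhitening** (for high-frequency, "double-detrended" analyses): a
Yule-Walker AR(p) fit with p chosen in 0..**5** by AIC
(`n·log v_p + 2p` on the Levinson-Durbin prediction variance); the output is
the residuals with the series mean added back, divided by their mean, so it
has mean exactly 1. Note that AIC admits a spurious order with roughly 15 %
probability per candidate, so even pure white noise selects order 0 only
about 70 % of the time; this is a property of the criterion, not of the
implementation.

## Sea ice

Monthly extent series (10^6 km²) are gap-filled by the arithmetic mean of
the same calendar month in the two adjacent years; gaps at the span edge or
with missing neighbours are errors. Seasonal variables are means of named
month sets; a leading `p` draws months from the year before the growth year
(`pSON` for year t averages Sep–Nov of t−1; `pDJF` combines Dec of t−1 with
Jan–Feb of t). A year missing any constituent month is omitted, never
partially averaged.

**Phenology.** Daily concentration grids cover one ice year per region
(a fixed March → February convention, so the summer minimum falls inside
the year). The pivot is the day of minimum extent at the chosen threshold
(first such day on ties). Per cell, the last retreat day (LRD) is the final
crossing from ≥ threshold to < threshold at or before the pivot; the first
advance day (FAD) is the first crossing back to ≥ threshold after it. Cells
lacking either crossing (perennially ice-covered or open) are excluded;
regional LRD/FAD are area-weighted means over the rest. Default threshold
**50 % SIC** (15 % supported), chosen for its larger intraseasonal
variation. No daily smoothing is applied before crossing detection; with
multiple crossings the *last* downward and *first* upward crossing are used,
matching the names literally. These conventions are documented substitutes
for the various published retreat/advance definitions.

## Climate and SPEI

Thornthwaite PET: `PET_m = 16 (L_m/12)(N_m/30)(10 T_m/I)^a` mm/month, zero
for `T_m ≤ 0`; `I = Σ (T_m/5)^1.514` over the year's above-zero months and
`a` the standard cubic in `I`. Day length comes from the solar-declination
formula at the month's middle day, with the polar day/night argument clamped
so `L_m ∈ [0, 24]` h. The high-temperature (> 26.5 °C) branch of the
original formulation is omitted as irrelevant at Arctic temperatures. Note
PET is monotone in a single month's temperature with everything else fixed,
but not under a uniform shift of all months (the heat index rises too).

SPEI at scale k: `D = P − PET` summed over a trailing k-month window
(supported scales include 1, 12, 24; the summer value used downstream is
the June–August mean of the 12-month series). Each calendar month is fitted
separately on the calibration years (default: the full span; ≥ 20 years
required) with a three-parameter log-logistic via unbiased
probability-weighted moments. The fit uses the generalized-logistic
parameterization (location ξ, scale α, shape κ = −τ₃), which coincides
with the classical log-logistic for right-skewed samples and remains valid
on the reflected branch — 12-month water-balance aggregates are close to
symmetric and sample skew of either sign occurs. Probabilities are clipped
to [1e-8, 1−1e-8] and the final index is clamped to **±3.09** (the 0.001
quantile), the standard convention: quantiles beyond the calibration
sample's resolution are not meaningful, and without the clamp a single
observation beyond the fitted distribution's finite bound can distort the
index variance.

## Linkage statistics

* **Screen**: Pearson r and two-sided p per (chronology, ice variable) over
  the analysis period, requiring ≥ 10 overlapping years;
  Benjamini–Hochberg adjustment within each chronology's row. The variable
  set is monthly previous-June → current-August (15 variables) plus the
  configured seasonal set, for the Pan-Arctic series and the chronology's
  assigned regional series.
* **Classification** uses raw p < **0.05** by default (the FDR-adjusted
  alternative is a switch): at least one significant negative correlation
  and no positive → *increaser*; symmetric → *decreaser*; none →
  *neutral*; both signs → *ambiguous* (surfaced rather than silently
  resolved).
* **k-means** (Lloyd's, 10 restarts, seeded) runs on the monthly Pan-Arctic
  correlation profiles; k is chosen by the largest second difference of the
  within-group sum of squares over k = 1..5.
* **Moving correlations**: 20-year windows, 1-year offset; significance
  when the percentile interval from **1000** pairs-bootstrap resamples
  excludes zero. Percentile intervals are the documented default; BCa is
  not implemented.
* **Epoch contrasts**: Welch's unequal-variance t with Satterthwaite df
  between 1979–1993 and 1994–2008.
* **Slope comparisons**: per-group OLS plus a pooled `y ~ x × group` model;
  the equality test is the F-test over the interaction terms.

## Mixed models and piecewise SEM

The node model is Gaussian with a random site intercept (optionally a
second intercept nested within site) and AR(1) residuals within groups
ordered by year:
`V_i = σ_b² J + σ_e² R(ρ)`, `R_st = ρ^{|t_s − t_t|}`. Estimation is exact
maximum likelihood: fixed effects are profiled out by GLS, and the 2–4
remaining parameters (log-variances, atanh ρ) are minimized with L-BFGS-B.
The implementation reproduces `nlme::lme(..., correlation = corAR1,
method = "ML")` and statsmodels' `MixedLM` (ML, no AR1) to the printed
precision, which the test suite verifies against both.

* Standardized coefficients: `β·sd(x)/sd(y)` with total standard
  deviations. Predictors are z-scored per site before SEM fitting; SPEI
  enters as-is (it is already an index); an optional square-root transform
  of the response is available for right-skewed index data.
* Coefficient tests use a containment-style df, `n_obs − n_groups − p`
  (p = slope terms).
* R²: marginal = fixed-effects variance share of
  (fixed + intercept variances + residual); conditional adds the random
  intercepts — the variance-components formulation.
* d-separation: the basis set contains every nonadjacent pair with at
  least one endogenous member (pairs of exogenous variables are free to
  covary); the topologically later variable is regressed on the earlier one
  plus the union of both variables' parents. Fisher's
  `C = −2 Σ ln p_i` is referred to χ²(2k); an empty basis set gives C = 0,
  p = 1. All paths are retained regardless of significance.
* AICc: per model `−2ℓ + 2k + 2k(k+1)/(n−k−1)`; for a whole SEM,
  `C + 2K n/(n − K − 1)` with K the total parameter count across node
  models. Akaike weights are `exp(−Δ_i/2)` normalized.

Known calibration properties: the claims in a basis set share data, so
their p-values are not exactly independent; the d-separation type-I error
measured over 200 simulated replicates (n = 300, 10 sites) is ≈ 0.05–0.06
at α = 0.05, which the acceptance suite checks. ML variance estimates carry
the usual O(p/n) downward bias; at the data sizes used here this is
negligible.

## Synthetic study generator

The generator produces everything the pipeline consumes — RWL ring data
with a metadata sidecar, monthly extent tables, daily concentration grids,
monthly site climate — from one seeded configuration, with the latent truth
(site labels, path coefficients, random effects) retained for testing.

Structure, in generation order:

* **Ice**: monthly extent = seasonal climatology (March maximum, September
  minimum) + an annual driver with piecewise linear decline (−0.01 before
  1995, −0.08 ×10⁶ km²/yr after, matching the observed acceleration) + AR(1)
  noise. Regional series are scaled copies with noise. Daily grids place
  per-cell retreat/advance days as linear functions of the standardized
  driver (less ice → earlier retreat, later advance).
* **Temperature**: the summer anomaly is constructed as
  `β_ice→temp · z(ice) + √(1−β²) · η` (unit variance), so the standardized
  ice → temperature path *equals* the configured coefficient by
  construction; default **−0.65**, sized so that forced sites are reliably
  classifiable from 30-year correlations at default replication (the
  chronology–ice correlation is bounded by this coupling). The anomaly is
  scaled to °C (1.5 °C per unit) and added to a sinusoidal monthly
  climatology; summer months get small (0.2 °C), other months larger
  (1.5 °C) monthly noise.
* **Precipitation**: log-normal monthly totals; the log-mean shifts by a
  per-responder coupling to z(ice): **+0.5** at decreaser sites (less ice →
  drier) and **−0.15** at increaser sites. The temp → SPEI and
  precip → SPEI links are *not* dialled directly: SPEI is computed
  mechanistically from the simulated climate through the package's own
  PET / water-balance / SPEI chain, so those paths emerge from the physics
  of the index (and the default SEM diagram includes them).
* **Growth**: per shrub, `w_t = f(r_t) · exp(g_t)` with
  `f(r) = 0.8·e^{−r/8} + 0.15` mm and
  `g_t = β_T·z(T_JJA) + β_S·z(SPEI12_JJA) + site + site-year + shrub +
  AR(1) residual`. Defaults: increasers β_T = 0.4, β_S = 0; decreasers
  β_T = 0.1, β_S = 0.45; site sd 0.10, site-year sd 0.08, shrub sd 0.10,
  residual sd 0.40 with ρ = 0.30 (giving within-site rbar ≈ 0.45–0.55 and
  chronology EPS ≈ 0.95 at 30 shrubs, in the range reported for real shrub
  chronologies). Germination years are normal(1966, 15) clipped to
  1952–1995, giving a mean age ≈ 42 at 2008 with realistic spread — the
  age-structure spread is what makes the regional curve identifiable.
* **Standardized-noise mode** (`standardize_noise=True`): the site-year
  disturbance is sized so the chronology-level log-growth signal has unit
  variance, making the configured growth paths standardized coefficients;
  the whole log signal is then multiplied by 0.3 so the exponential stays
  in its near-linear range (at unit log-variance the level/log
  transformation attenuates standardized coefficients by ~25 %). This mode
  is what the SEM parameter-recovery experiments use; the default mode
  instead keeps noise at realistic magnitudes so the responder contrast is
  strong, which is the classification experiment's requirement.

What the generator does **not** emulate: spatial autocorrelation between
regions or sites, satellite sensor artifacts and the polar observation
hole, measurement or cross-dating error in ring widths, snow, herbivory or
disturbance covariates, and age-dependent (as opposed to size-dependent)
growth trends. Passing tests therefore demonstrate that the *methods*
recover known structure under the stated noise model, not that real data
meet these assumptions.

## Problem sizes

The test suite runs the full default study (22 sites × 30 shrubs ×
1950–2008) once for responder recovery, a 13-site standardized-noise study
for SEM path recovery, 200 replicates of n = 300 for d-separation
calibration, and 60-year series for SPEI calibration; the whole suite
completes in a few minutes on one CPU, and `scripts/acceptance.py` in about
two. These sizes mirror the target study design (23 chronologies, ~33
sections each, 30-year analysis window) at full scale; only replicate
counts for calibration experiments are chosen for desk-scale runtime.

## Known limitations

* Single-curve dRCS only; age-RCS and multiple fast/slow-curve variants,
  variance stabilization and pith-offset estimation are out of scope.
* Chronology trend that is collinear with the population's radius growth
  can be partially absorbed into the regional curve at low replication
  (trend distortion); the signal-free iteration reduces but cannot
  eliminate this when age structure is narrow.
* The RWL parser handles whitespace-delimited decadal files with integer
  fields; fixed-column headers and site description blocks are not parsed.
* Phenology assumes clean daily coverage of the ice year; no smoothing,
  polar-hole handling or regridding.
* The SPEI calibration period defaults to the full supplied span; results
  are sensitive to that choice when trends are strong.
* d-separation p-values treat basis-set claims as independent; with many
  correlated claims Fisher's C is only approximately χ².
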