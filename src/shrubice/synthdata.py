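"""Synthetic study generator with known ground truth.

Emulates the data structure of a pan-Arctic shrub-ring / sea-ice
synthesis so that every pipeline stage runs without external downloads:

* a pan-Arctic monthly sea-ice extent series with a seasonal cycle, a
  piecewise linear decline (steeper after a mid-1990s breakpoint) and
  AR(1) noise, plus scaled regional series;
* small daily sea-ice concentration grids per region whose per-cell
  retreat/advance days track the extent anomaly (less ice -> earlier
  retreat, later advance);
* monthly site climate: summer temperature anomalies constructed as
  ``beta_ice_temp * z(ice) + sqrt(1 - beta^2) * noise`` so the
  standardized ice->temperature path equals the configured coefficient;
  log-normal precipitation optionally coupled to the ice anomaly
  (strongly and positively at decreaser sites, weakly and negatively at
  increaser sites).  SPEI couplings (temp->SPEI, precip->SPEI) are not
  dialled directly: SPEI is computed mechanistically from the simulated
  climate through the package's own PET / water-balance / SPEI chain;
* shrub populations per site: ring widths follow a diameter-dependent
  expected-growth curve ``w0*exp(-r/r0) + wmin`` multiplied by
  ``exp(g_t)`` where the log growth signal ``g_t`` combines the
  configured temperature and SPEI paths (computed on the site's own
  simulated climate), a site intercept, a shrub intercept, a shared
  site-year disturbance and an AR(1) shrub-level residual.

Increaser sites carry a positive temperature path (growth rises as ice
declines, via warming); decreaser sites carry a positive SPEI path with
precipitation positively coupled to ice (growth falls as ice declines,
via drying).  With ``standardize_noise=True`` the site-year disturbance
is sized so the chronology-level log-growth signal has unit variance,
making the configured paths standardized coefficients that the SEM
stage should recover directly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from .detrend import Chronology
from .ringio import RingSeries, write_rwl
from .seaice import IceConcentrationGrid, MonthlyIceSeries, write_monthly_extent

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedStudy",
    "simulate_system",
    "write_study",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    seed: int = 0
    year_start: int = 1950
    year_end: int = 2008
    analysis_period: tuple[int, int] = (1979, 2008)

    n_increaser_sites: int = 13
    n_decreaser_sites: int = 9
    n_neutral_sites: int = 0
    shrubs_per_site: int = 30
    germination_mean: float = 1966.0
    germination_sd: float = 15.0
    germination_range: tuple[int, int] = (1952, 1995)

    # expected ring width (mm) vs stem radius (mm): w0*exp(-r/r0) + wmin
    curve_w0: float = 0.8
    curve_r0: float = 8.0
    curve_wmin: float = 0.15

    # standardized path coefficients (z-scale)
    beta_ice_temp: float = -0.65
    beta_temp_rwi_increaser: float = 0.4
    beta_temp_rwi_decreaser: float = 0.1
    beta_spei_rwi_increaser: float = 0.0
    beta_spei_rwi_decreaser: float = 0.45
    beta_ice_rwi_direct: float = 0.0
    # log-precip shift per z(ice)
    precip_coupling_increaser: float = -0.15
    precip_coupling_decreaser: float = 0.5

    # noise (log growth scale unless stated)
    site_sd: float = 0.10
    shrub_sd: float = 0.10
    site_year_sd: float = 0.08
    resid_sd: float = 0.40
    resid_rho: float = 0.30
    standardize_noise: bool = False
    # with standardize_noise, the unit-variance log signal is multiplied by
    # this scale so exp() stays near-linear and standardized paths survive
    # the log -> level transformation
    signal_scale: float = 0.3

    # sea ice (10^6 km^2)
    ice_mean: float = 11.0
    ice_seasonal_amplitude: float = 3.5
    ice_trend_early: float = -0.01
    ice_trend_late: float = -0.08
    ice_breakpoint: int = 1995
    ice_noise_sd: float = 0.25
    ice_noise_rho: float = 0.5
    ice_monthly_noise_sd: float = 0.10
    regions: tuple[str, ...] = ("west", "east")
    regional_scale: float = 0.12
    regional_offset: float = 0.5

    # climate
    temp_mean_annual: float = -8.0
    temp_seasonal_amplitude: float = 14.0
    temp_anom_scale: float = 1.5        # deg C per unit summer anomaly
    temp_jja_noise_sd: float = 0.2      # deg C, monthly, summer
    temp_other_noise_sd: float = 1.5    # deg C, monthly, other months
    precip_log_mean: float = math.log(30.0)
    precip_log_noise_sd: float = 0.25
    spei_scale: int = 12

    # concentration grids
    cells_per_region: int = 3
    cell_areas: tuple[float, ...] = (400.0, 625.0, 900.0)
    retreat_base: float = 150.0
    retreat_per_z: float = 12.0
    advance_base: float = 300.0
    advance_per_z: float = -10.0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"non-finite config parameter {name}")
        if not (abs(self.resid_rho) < 1 and abs(self.ice_noise_rho) < 1):
            raise ValueError("|rho| must be < 1")
        for sd in (self.site_sd, self.shrub_sd, self.site_year_sd, self.resid_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")
        if self.curve_w0 + self.curve_wmin <= 0 or self.curve_wmin < 0:
            raise ValueError("growth curve must be positive")

    def growth_curve(self, radius: np.ndarray) -> np.ndarray:
        return self.curve_w0 * np.exp(-np.asarray(radius, float) / self.curve_r0) + self.curve_wmin


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    site_labels: dict[str, str]
    site_effects: dict[str, float]
    shrub_effects: dict[str, float]
    germination_years: dict[str, int]
    z_ice: pd.Series                    # annual standardized extent anomaly
    site_temp_jja_z: dict[str, pd.Series]
    site_spei_jja_z: dict[str, pd.Series]
    site_log_signal: dict[str, pd.Series]


@dataclass
class SimulatedStudy:
    ice: dict[str, MonthlyIceSeries]
    grids: dict[str, dict[int, IceConcentrationGrid]]
    climate: dict[str, pd.DataFrame]
    series: list[RingSeries]
    site_meta: pd.DataFrame
    truth: SyntheticTruth


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation sd."""
    e = rng.normal(0.0, sd, n)
    if n == 0 or rho == 0:
        return e
    x = np.empty(n)
    x[0] = e[0]
    innov = math.sqrt(1.0 - rho * rho)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov * e[t]
    return x


def simulate_system(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Generate a full synthetic study from the configuration (seeded)."""
    cfg = config or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    n_years = years.size

    # --- sea ice driver ------------------------------------------------
    drift = np.where(
        years <= cfg.ice_breakpoint,
        cfg.ice_trend_early * (years - cfg.year_start),
        cfg.ice_trend_early * (cfg.ice_breakpoint - cfg.year_start)
        + cfg.ice_trend_late * (years - cfg.ice_breakpoint),
    )
    driver = drift + _ar1(rng, n_years, cfg.ice_noise_rho, cfg.ice_noise_sd)
    lo, hi = cfg.analysis_period
    ref = driver[(years >= lo) & (years <= hi)]
    z_ice = pd.Series((driver - ref.mean()) / ref.std(), index=pd.Index(years, name="year"))

    months = np.arange(1, 13)
    clim_m = cfg.ice_mean + cfg.ice_seasonal_amplitude * np.cos(2 * np.pi * (months - 3) / 12.0)
    rows = []
    for i, y in enumerate(years):
        ext = clim_m + driver[i] + rng.normal(0, cfg.ice_monthly_noise_sd, 12)
        for m in months:
            rows.append((int(y), int(m), max(float(ext[m - 1]), 0.05)))
    pan = MonthlyIceSeries("panarctic", pd.DataFrame(rows, columns=["year", "month", "extent"]))
    ice = {"panarctic": pan}
    for r_i, region in enumerate(cfg.regions):
        df = pan.records.copy()
        df["extent"] = (
            cfg.regional_scale * df["extent"]
            + cfg.regional_offset * (1.0 + 0.2 * r_i)
            + rng.normal(0, 0.02, len(df))
        ).clip(lower=0.01)
        ice[region] = MonthlyIceSeries(region, df)

    # --- concentration grids -------------------------------------------
    areas = np.asarray(cfg.cell_areas[: cfg.cells_per_region], float)
    grids: dict[str, dict[int, IceConcentrationGrid]] = {}
    days = np.arange(1, 366)
    for region in cfg.regions:
        cell_off = np.linspace(-6.0, 6.0, cfg.cells_per_region)
        grids[region] = {}
        for i, y in enumerate(years):
            conc = np.empty((days.size, cfg.cells_per_region))
            for c in range(cfg.cells_per_region):
                r_day = cfg.retreat_base + cfg.retreat_per_z * z_ice.iloc[i] + cell_off[c]
                a_day = cfg.advance_base + cfg.advance_per_z * z_ice.iloc[i] + cell_off[c]
                r_day = float(np.clip(r_day + rng.normal(0, 2.0), 40, 200))
                a_day = float(np.clip(a_day + rng.normal(0, 2.0), 230, 350))
                conc[:, c] = np.where((days >= r_day) & (days < a_day), 5.0, 95.0)
            grids[region][int(y)] = IceConcentrationGrid(days, conc, areas)

    # --- sites ----------------------------------------------------------
    labels = (
        ["increaser"] * cfg.n_increaser_sites
        + ["decreaser"] * cfg.n_decreaser_sites
        + ["neutral"] * cfg.n_neutral_sites
    )
    site_ids = []
    for lab_count, (prefix, n) in zip(
        range(3),
        [("INC", cfg.n_increaser_sites), ("DEC", cfg.n_decreaser_sites), ("NEU", cfg.n_neutral_sites)],
    ):
        site_ids += [f"{prefix}{i+1:02d}" for i in range(n)]
    site_labels = dict(zip(site_ids, labels))

    meta_rows = []
    climate: dict[str, pd.DataFrame] = {}
    site_temp_z: dict[str, pd.Series] = {}
    site_spei_z: dict[str, pd.Series] = {}
    site_signal: dict[str, pd.Series] = {}
    site_effects: dict[str, float] = {}
    shrub_effects: dict[str, float] = {}
    germ_years: dict[str, int] = {}
    series: list[RingSeries] = []

    # warmest in July: cos peaks at m = 7
    temp_clim = cfg.temp_mean_annual + cfg.temp_seasonal_amplitude * np.cos(
        2 * np.pi * (months - 7) / 12.0
    )

    for s_i, sid in enumerate(site_ids):
        label = site_labels[sid]
        region = cfg.regions[s_i % len(cfg.regions)]
        latitude = float(rng.uniform(58.0, 80.0))
        species = "Betula" if s_i % 2 == 0 else "Salix"
        soil = "moist" if (s_i // 2) % 2 == 0 else "dry"
        meta_rows.append((sid, species, soil, latitude, float(rng.uniform(-150, 40)), region))

        # summer temperature anomaly with exact standardized ice path
        b = cfg.beta_ice_temp if label != "neutral" else 0.0
        eta = rng.normal(0, 1, n_years)
        anom = b * z_ice.to_numpy() + math.sqrt(max(1.0 - b * b, 0.0)) * eta

        kappa = {
            "increaser": cfg.precip_coupling_increaser,
            "decreaser": cfg.precip_coupling_decreaser,
            "neutral": 0.0,
        }[label]
        crows = []
        for i, y in enumerate(years):
            for m in months:
                if m in (6, 7, 8):
                    t = temp_clim[m - 1] + cfg.temp_anom_scale * anom[i] + rng.normal(
                        0, cfg.temp_jja_noise_sd
                    )
                else:
                    t = temp_clim[m - 1] + cfg.temp_anom_scale * anom[i] + rng.normal(
                        0, cfg.temp_other_noise_sd
                    )
                p = math.exp(
                    cfg.precip_log_mean
                    + kappa * z_ice.iloc[i]
                    + rng.normal(0, cfg.precip_log_noise_sd)
                )
                crows.append((sid, int(y), int(m), float(t), float(p)))
        cdf = pd.DataFrame(crows, columns=["site_id", "year", "month", "tmean_c", "precip_mm"])
        climate[sid] = cdf

        pet = climate_mod.thornthwaite_pet(cdf, latitude)
        d = climate_mod.water_balance(cdf, pet)
        sp = climate_mod.spei(d, cfg.spei_scale)
        spei_jja = climate_mod.jja_aggregate(sp.values["spei"])
        temp_jja = climate_mod.jja_aggregate(cdf.set_index(["year", "month"])["tmean_c"])

        def _z(s: pd.Series) -> pd.Series:
            return (s - s.mean()) / s.std(ddof=0)

        zt = _z(temp_jja)
        zs = _z(spei_jja)
        site_temp_z[sid] = zt
        site_spei_z[sid] = zs

        bt = {"increaser": cfg.beta_temp_rwi_increaser, "decreaser": cfg.beta_temp_rwi_decreaser, "neutral": 0.0}[label]
        bs = {"increaser": cfg.beta_spei_rwi_increaser, "decreaser": cfg.beta_spei_rwi_decreaser, "neutral": 0.0}[label]
        common = zt.index.intersection(zs.index)
        path = (
            bt * zt.loc[common]
            + bs * zs.loc[common]
            + cfg.beta_ice_rwi_direct * z_ice.loc[common]
        )
        if cfg.standardize_noise:
            v = float(path.var(ddof=0))
            sy_sd = math.sqrt(max(1.0 - v, 0.04))
        else:
            sy_sd = cfg.site_year_sd
        site_year = pd.Series(rng.normal(0, sy_sd, common.size), index=common)
        site_eff = float(rng.normal(0, cfg.site_sd))
        site_effects[sid] = site_eff
        signal = path + site_year + site_eff
        if cfg.standardize_noise:
            signal = signal * cfg.signal_scale
        site_signal[sid] = signal

        grow_years = signal.index.to_numpy()
        for k in range(cfg.shrubs_per_site):
            shrub_id = f"{sid}S{k+1:02d}"
            g = int(np.clip(round(rng.normal(cfg.germination_mean, cfg.germination_sd)),
                            *cfg.germination_range))
            germ_years[shrub_id] = g
            sh_eff = float(rng.normal(0, cfg.shrub_sd))
            shrub_effects[shrub_id] = sh_eff
            yrs = grow_years[grow_years >= g]
            resid = _ar1(rng, yrs.size, cfg.resid_rho, cfg.resid_sd)
            widths = np.empty(yrs.size)
            radius = 0.0
            for t, y in enumerate(yrs):
                w = float(cfg.growth_curve(radius)) * math.exp(
                    float(signal.loc[y]) + sh_eff + resid[t]
                )
                widths[t] = w
                radius += w
            series.append(
                RingSeries(
                    series_id=shrub_id,
                    shrub_id=shrub_id,
                    site_id=sid,
                    species=species,
                    first_year=int(yrs[0]),
                    widths=widths,
                    soil_class=soil,
                    latitude=latitude,
                    ice_region_id=region,
                )
            )

    site_meta = pd.DataFrame(
        meta_rows,
        columns=["site_id", "species", "soil_class", "latitude", "longitude", "ice_region_id"],
    )
    truth = SyntheticTruth(
        config=cfg,
        site_labels=site_labels,
        site_effects=site_effects,
        shrub_effects=shrub_effects,
        germination_years=germ_years,
        z_ice=z_ice,
        site_temp_jja_z=site_temp_z,
        site_spei_jja_z=site_spei_z,
        site_log_signal=site_signal,
    )
    return SimulatedStudy(
        ice=ice, grids=grids, climate=climate, series=series, site_meta=site_meta, truth=truth
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict:
    """Write the study in the pipeline's input formats; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_rwl(study.series, outdir / "rings.rwl", precision=0.001)
    study.site_meta.to_csv(outdir / "site_metadata.csv", index=False)
    write_monthly_extent(study.ice, outdir / "ice_monthly.csv")
    pd.concat(study.climate.values()).to_csv(outdir / "climate.csv", index=False)
    grid_files = []
    for region, per_year in study.grids.items():
        rows = []
        for y in sorted(per_year):
            g = per_year[y]
            for c in range(g.cell_area.size):
                for di, day in enumerate(g.days):
                    rows.append((y, int(day), f"{region}C{c}", g.conc[di, c], g.cell_area[c]))
        fn = outdir / f"sic_grid_{region}.csv"
        pd.DataFrame(
            rows, columns=["ice_year", "day", "cell_id", "concentration", "cell_area"]
        ).to_csv(fn, index=False)
        grid_files.append(fn.name)
    manifest = {
        "seed": study.truth.config.seed,
        "files": ["rings.rwl", "site_metadata.csv", "ice_monthly.csv", "climate.csv", *grid_files],
        "site_labels": study.truth.site_labels,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def make_fixture(name: str):
    """Deterministic small test datasets used across the test suite."""
    if name == "toy_rwl":
        return [
            RingSeries("S1", 1990, np.round(np.linspace(1.0, 0.4, 21), 2)),
            RingSeries("S2", 1995, np.round(np.linspace(0.8, 0.5, 14), 2)),
        ]
    if name == "toy_ice_grid":
        days = np.arange(1, 366)
        conc = np.empty((365, 2))
        conc[:, 0] = np.where((days >= 100) & (days < 300), 5.0, 95.0)
        conc[:, 1] = np.where((days >= 200) & (days < 310), 5.0, 95.0)
        return IceConcentrationGrid(days, conc, np.array([1.0, 3.0]))
    if name == "toy_climate":
        rows = []
        for y in (2000, 2001):
            for m in range(1, 13):
                t = -8.0 + 14.0 * math.cos(2 * math.pi * (m - 7) / 12.0)
                rows.append(("SITE1", y, m, t, 30.0))
        return pd.DataFrame(rows, columns=["site_id", "year", "month", "tmean_c", "precip_mm"])
    if name == "tiny_study":
        cfg = SimulationConfig(
            seed=17,
            n_increaser_sites=2,
            n_decreaser_sites=2,
            n_neutral_sites=0,
            shrubs_per_site=8,
            year_start=1970,
        )
        return simulate_system(cfg)
    raise ValueError(f"unknown fixture {name!r}")
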