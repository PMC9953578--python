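"""Synthetic occurrence, trait and climate data with known ground truth.

The generator emulates the sampling design the analysis pipeline expects:
two sampling periods, a handful of sites spanning a wide elevation range,
coarse historical elevation bins replicated for the resurvey, species with
Gaussian thermal niches (and an optional logistic alternative), a trait
table with the twelve canonical trait columns, and two-resolution monthly
temperature grids linked by a known affine bias and a known between-period
warming offset.  Everything is reproducible from the seed alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import xarray as xr

from resurvey import climate as clim
from resurvey.records import RECORD_COLUMNS, SpeciesRegistry
from resurvey.traits import TRAIT_COLUMNS


@dataclasses.dataclass(frozen=True)
class ScenarioConfig:
    n_species: int = 28
    n_sites: int = 11
    elev_range: tuple[float, float] = (1100.0, 2899.0)
    bins_per_site: int = 3
    site_band_width: float = 900.0  # elevation extent sampled per site
    periods: tuple[tuple[str, tuple[int, ...]], ...] = (
        ("1935/1936", (1935, 1936)),
        ("2020", (2020,)),
    )
    warming: float = 1.76  # K between period means
    gradient: float = -6.68  # K per km
    sea_level_temp: float = 14.0  # spring temperature at 0 masl, period 1
    niche_sd: float = 1.8  # K
    p_max: float = 0.9
    parasite_fraction: float = 0.25
    parasite_recent_multiplier: float = 0.1
    sti_noise_sd: float = 0.3
    mean_count: float = 3.0
    niche_model: str = "gaussian"  # or "logistic"
    spatial_noise_sd: float = 0.0  # climate field noise, K
    interannual_sd: float = 0.8  # shared year-to-year anomaly, K
    coarse_factor: int = 4
    fine_shape: tuple[int, int] = (24, 24)  # (ny, nx)
    bias_slope: float = 1.1
    bias_intercept: float = -0.8
    years: tuple[int, int] = (1905, 2020)  # climate coverage (inclusive)
    splice_year: int = 1961

    @property
    def period_labels(self) -> list[str]:
        return [p for p, _ in self.periods]

    def period_years(self, label: str) -> tuple[int, ...]:
        return dict(self.periods)[label]


@dataclasses.dataclass
class SpeciesPool:
    registry: SpeciesRegistry
    traits: pd.DataFrame  # species x 12 traits
    niches: pd.DataFrame  # T_opt, sigma, p_max, m_<period> columns


def spring_temperature(
    elev: float, period_index: int, config: ScenarioConfig
) -> float:
    """Analytic lapse-rate spring temperature for a unit elevation."""
    t = config.sea_level_temp + config.gradient * elev / 1000.0
    if period_index > 0:
        t += config.warming
    return t


def gen_species_pool(config: ScenarioConfig, seed: int = 0) -> SpeciesPool:
    rng = np.random.default_rng(seed)
    n = config.n_species
    if n < 5:
        raise ValueError("need at least 5 species")
    names = [f"sp{i + 1:02d}" for i in range(n)]
    lo, hi = config.elev_range
    t_hi = config.sea_level_temp + config.gradient * lo / 1000.0
    t_lo = config.sea_level_temp + config.gradient * hi / 1000.0
    t_opt = rng.uniform(t_lo, t_hi, size=n)
    sti = t_opt + rng.normal(0.0, config.sti_noise_sd, size=n)
    n_parasites = int(round(config.parasite_fraction * n))
    parasites = rng.choice(n, size=n_parasites, replace=False)
    is_par = np.zeros(n, dtype=bool)
    is_par[parasites] = True

    nest_above = rng.integers(0, 2, size=n)
    habitat_open = rng.integers(0, 2, size=n)
    micro_wide = rng.integers(0, 2, size=n)
    macro_ind = rng.integers(0, 2, size=n)
    traits = pd.DataFrame(
        {
            "proboscis_length": rng.normal(9.0, 2.0, size=n).clip(4, 18),
            "body_size": rng.normal(14.0, 3.0, size=n).clip(8, 24),
            "nest_above": nest_above,
            "nest_below": 1 - nest_above,
            "socio_parasitic": is_par.astype(int),
            "habitat_open": habitat_open,
            "habitat_forest_edge": 1 - habitat_open,
            "STI": sti,
            "micro_wide": micro_wide,
            "micro_cold": 1 - micro_wide,
            "macro_indiscriminate": macro_ind,
            "macro_alpine": 1 - macro_ind,
        },
        index=pd.Index(names, name="species"),
    )[TRAIT_COLUMNS].astype(float)

    niches = pd.DataFrame(
        {"T_opt": t_opt, "sigma": config.niche_sd, "p_max": config.p_max},
        index=traits.index,
    )
    for i, label in enumerate(config.period_labels):
        m = np.ones(n)
        if i > 0:
            m[is_par] = config.parasite_recent_multiplier
        niches[f"m_{label}"] = m

    registry = SpeciesRegistry(
        canonical=frozenset(names),
        synonyms={f"{names[0]} (old name)": names[0]},
        parasites=frozenset(traits.index[is_par]),
        drop=frozenset({"indet. sp."}),
    )
    return SpeciesPool(registry=registry, traits=traits, niches=niches)


def occupancy_probability(
    temp: float | np.ndarray, niches: pd.DataFrame, config: ScenarioConfig
) -> np.ndarray:
    t_opt = niches["T_opt"].to_numpy()
    sigma = niches["sigma"].to_numpy()
    p_max = niches["p_max"].to_numpy()
    if config.niche_model == "gaussian":
        resp = np.exp(-((temp - t_opt) ** 2) / (2.0 * sigma**2))
    elif config.niche_model == "logistic":
        resp = 1.0 / (1.0 + np.exp(np.abs(temp - t_opt) / sigma - 2.0))
    else:
        raise ValueError(f"unknown niche model {config.niche_model!r}")
    return p_max * resp


def scenario_units(config: ScenarioConfig) -> pd.DataFrame:
    """Deterministic site/bin/period layout with true spring temperatures."""
    lo, hi = config.elev_range
    sites = [f"S{i + 1:02d}" for i in range(config.n_sites)]
    rows = []
    for si, site in enumerate(sites):
        if config.n_sites > 1:
            base = lo + (hi - lo - config.site_band_width) * si / (config.n_sites - 1)
        else:
            base = lo
        edges = np.linspace(
            base, base + config.site_band_width, config.bins_per_site + 1
        )
        for b in range(config.bins_per_site):
            e_lo, e_hi = float(edges[b]), float(edges[b + 1])
            mean_elev = (e_lo + e_hi) / 2.0
            for pi, (label, years) in enumerate(config.periods):
                year = years[si % len(years)]
                rows.append(
                    {
                        "site": site, "elev_low": round(e_lo), "elev_high": round(e_hi),
                        "mean_elev": mean_elev, "period": label, "year": year,
                        "spring_temp": spring_temperature(mean_elev, pi, config),
                        "period_index": pi,
                    }
                )
    return pd.DataFrame(rows)


def gen_units_and_records(
    pool: SpeciesPool,
    config: ScenarioConfig,
    seed: int = 0,
    unit_temps: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence records in the harmonization CSV schema, plus unit truth.

    ``unit_temps`` may supply spring temperatures per scenario unit (e.g.
    from the climate pipeline); by default the analytic lapse-rate
    temperatures are used.
    """
    rng = np.random.default_rng(seed)
    units = scenario_units(config)
    if unit_temps is not None:
        units = units.assign(spring_temp=np.asarray(unit_temps, dtype=float))
    records = []
    for _, unit in units.iterrows():
        p = occupancy_probability(unit["spring_temp"], pool.niches, config)
        p = p * pool.niches[f"m_{unit['period']}"].to_numpy()
        present = rng.random(p.size) < p
        for sp in pool.niches.index[present]:
            # zero-truncated Poisson count
            lam = config.mean_count
            count = 0
            while count == 0:
                count = int(rng.poisson(lam))
            records.append(
                {
                    "species": sp,
                    "count": count,
                    "site": unit["site"],
                    "year": int(unit["year"]),
                    "month": int(rng.integers(6, 9)),
                    "day": int(rng.integers(1, 29)),
                    "elev_low": unit["elev_low"],
                    "elev_high": unit["elev_high"],
                }
            )
    df = pd.DataFrame(records, columns=RECORD_COLUMNS)
    for col in ("count", "month", "day"):
        df[col] = df[col].astype("Int64")
    return df, units


def gen_climate(config: ScenarioConfig, seed: int = 0) -> dict:
    """Two-resolution monthly stacks, DEMs, and the true generating fields.

    The fine stack is ``seasonal + warming step + gradient * z + noise``;
    the coarse stack is the block-aggregated fine field pushed through the
    inverse of a known affine bias, so that fitting coarse -> fine recovers
    (bias_slope, bias_intercept).  The warming step is 0 through the
    historical period and exactly ``warming`` from the splice era onward.
    """
    rng = np.random.default_rng(seed)
    ny, nx = config.fine_shape
    k = config.coarse_factor
    if ny % k or nx % k:
        raise ValueError("fine_shape must be divisible by coarse_factor")
    x = np.arange(nx) * 100.0  # 100 m spacing
    y = np.arange(ny) * 100.0
    lo, hi = config.elev_range
    zy = np.linspace(lo, hi, ny)[:, None]
    zx = 60.0 * np.sin(np.linspace(0, 3 * np.pi, nx))[None, :]
    dem = xr.DataArray(
        zy + zx, dims=("y", "x"), coords={"y": y, "x": x}, name="elevation"
    )
    years = np.arange(config.years[0], config.years[1] + 1)
    months = np.arange(1, 13)
    seasonal = 8.0 * np.sin((months - 4) / 12.0 * 2 * np.pi)
    # 30-year index windows end at the first year of each sampling period
    hist_last = min(
        y for _p, ys in config.periods[:1] for y in ys
    ) if config.periods else 1935
    step = np.where(
        years < config.splice_year,
        np.where(years <= hist_last + 3, 0.0, 0.0),
        config.warming,
    )
    # ramp between the historical period and the splice keeps the series
    # physically plausible without touching either 30-year mean
    ramp_years = (years >= hist_last) & (years < config.splice_year)
    step = step.astype(float)
    step[ramp_years] = config.warming * (
        (years[ramp_years] - hist_last) / (config.splice_year - hist_last)
    )

    # shared interannual anomaly (identical in both datasets); demeaned
    # per month inside each 30-year index window so the realized
    # between-period warming equals the configured offset exactly
    eta = (
        rng.normal(0.0, config.interannual_sd, size=(len(years), 12))
        if config.interannual_sd > 0
        else np.zeros((len(years), 12))
    )
    last = int(years[-1])
    windows = ((hist_last - 29, hist_last), (last - 29, last))
    for w0, w1 in windows:
        sel = (years >= w0) & (years <= w1)
        if sel.any():
            eta[sel] -= eta[sel].mean(axis=0, keepdims=True)

    base = config.sea_level_temp + config.gradient * dem.values / 1000.0
    fine_vals = (
        base[None, None, :, :]
        + seasonal[None, :, None, None]
        + step[:, None, None, None]
        + eta[:, :, None, None]
    )
    if config.spatial_noise_sd > 0:
        fine_vals = fine_vals + rng.normal(
            0.0, config.spatial_noise_sd, size=fine_vals.shape
        )
    fine = clim.monthly_grid(fine_vals, years, x, y)

    # block aggregation to the coarse grid
    agg = fine_vals.reshape(len(years), 12, ny // k, k, nx // k, k).mean(
        axis=(3, 5)
    )
    coarse_vals = (agg - config.bias_intercept) / config.bias_slope
    cx = x.reshape(nx // k, k).mean(axis=1)
    cy = y.reshape(ny // k, k).mean(axis=1)
    coarse = clim.monthly_grid(coarse_vals, years, cx, cy)
    coarse_elev = xr.DataArray(
        dem.values.reshape(ny // k, k, nx // k, k).mean(axis=(1, 3)),
        dims=("y", "x"), coords={"y": cy, "x": cx}, name="elevation",
    )
    return {
        "fine": fine,
        "coarse": coarse,
        "dem": dem,
        "coarse_elev": coarse_elev,
        "years": years,
        "warming_step": step,
        "index_windows": windows,
    }


def ground_truth(pool: SpeciesPool, config: ScenarioConfig) -> dict:
    """Analytic expectations for parameter-recovery assertions."""
    units = scenario_units(config)
    truth: dict = {
        "warming": config.warming,
        "gradient": config.gradient,
        "niches": pool.niches,
    }
    richness = {}
    parasite_share = {}
    par = pool.traits["socio_parasitic"].to_numpy() > 0
    for label in config.period_labels:
        sub = units[units["period"] == label]
        miss = np.ones(len(pool.niches))
        shares = []
        for _, unit in sub.iterrows():
            p = occupancy_probability(unit["spring_temp"], pool.niches, config)
            p = p * pool.niches[f"m_{label}"].to_numpy()
            miss *= 1.0 - p
            tot = p.sum()
            if tot > 0:
                shares.append(p[par].sum() / tot)
        occupancy = 1.0 - miss
        richness[label] = int((occupancy > 1e-9).sum())
        parasite_share[label] = float(np.mean(shares)) if shares else np.nan
    truth["richness"] = richness
    truth["parasite_share"] = parasite_share
    return truth
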