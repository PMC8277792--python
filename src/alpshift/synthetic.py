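"""Synthetic mountain landscapes, warming climates, and virtual species records.

The generator builds the kind of study system the elevational-shift analysis
assumes: a digital elevation model with a wide altitudinal gradient, monthly
climate that cools with elevation at a fixed lapse rate and warms year on year,
an insolation proxy driven by slope and aspect, and species whose occurrence
records track their climatic optimum uphill as the climate warms.  Because
every species' niche and the climate trend are known exactly, every downstream
statistic (z_alt, z_range, z_VMR, z_skew) has a known expected value: under a
warming rate ``w`` (degC/yr) and lapse rate ``L`` (degC/m) an isotherm — and with
it a thermally constrained species — is expected to move uphill at ``w / L``
metres per year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid, slope_aspect

logger = logging.getLogger(__name__)

MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])


@dataclass
class MonthlyClimate:
    """One calendar year of monthly climate grids on a shared geometry.

    tmin/tmean/tmax are (12, ny, nx) arrays in degC, prec is cumulative monthly
    precipitation in mm.  Cell-wise tmin <= tmean <= tmax and prec >= 0.
    """

    year: int
    tmin: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        for name in ("tmin", "tmean", "tmax", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 3 or arr.shape[0] != 12:
                raise ValueError(f"{name} must be a (12, ny, nx) array")
            setattr(self, name, arr)
        if np.any(self.tmin > self.tmean) or np.any(self.tmean > self.tmax):
            raise ValueError("monthly temperatures must satisfy tmin <= tmean <= tmax")
        if np.any(self.prec < 0):
            raise ValueError("precipitation must be non-negative")

    def annual_tmean(self) -> np.ndarray:
        return self.tmean.mean(axis=0)

    def annual_prec(self) -> np.ndarray:
        return self.prec.sum(axis=0)


@dataclass
class SpeciesTraits:
    """Categorical ecological traits used in the trait models."""

    euryocy: str = "specialist"          # generalist | specialist
    dispersal: str = "sedentary"         # sedentary | intermediate | mobile
    endangerment: str = "threatened"     # threatened | least_concern

    _LEVELS = {
        "euryocy": ("generalist", "specialist"),
        "dispersal": ("sedentary", "intermediate", "mobile"),
        "endangerment": ("threatened", "least_concern"),
    }

    def __post_init__(self) -> None:
        for name, levels in self._LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValueError(f"{name} must be one of {levels}")


@dataclass
class SpeciesSpec:
    """A virtual species: a Gaussian climatic niche plus sampling parameters.

    thermal_optimum/thermal_breadth describe a Gaussian suitability kernel on
    annual mean temperature (degC); prec_optimum/prec_breadth the analogous
    kernel on annual precipitation (mm).  ``detectability`` scales the expected
    number of records per year; ``records_per_year`` is the Poisson mean at
    detectability 1.
    """

    name: str
    thermal_optimum: float
    thermal_breadth: float
    prec_optimum: float = 1200.0
    prec_breadth: float = 600.0
    detectability: float = 1.0
    records_per_year: float = 10.0
    traits: SpeciesTraits = field(default_factory=SpeciesTraits)
    #: fraction of the regional warming the species fails to tolerate in place:
    #: 1.0 tracks the isotherm fully (uphill velocity = warming/lapse), 0.0
    #: acclimatises entirely and does not move.  Used to program trait-dependent
    #: shift rates (e.g. mobile species tracking more than sedentary ones).
    tracking: float = 1.0

    def __post_init__(self) -> None:
        if self.thermal_breadth <= 0 or self.prec_breadth <= 0:
            raise ValueError("niche breadths must be positive")
        if not (0 < self.detectability <= 1):
            raise ValueError("detectability must be in (0, 1]")
        if not (0 <= self.tracking <= 1):
            raise ValueError("tracking must be in [0, 1]")


def make_dem(
    nx: int,
    ny: int,
    cell_size: float = 100.0,
    relief: dict | None = None,
    seed: int = 0,
    hypsometry: str = "uniform",
) -> Grid:
    """Generate a synthetic mountain DEM.

    Relief is a sum of randomly oriented cosine ridges plus a smoothed
    Gaussian random field, rescaled so elevations span exactly
    [base_elev, base_elev + amplitude].

    With ``hypsometry="uniform"`` (default) elevations are additionally
    rank-equalized: the ridge/valley topology is preserved (the transform is
    monotone) but the hypsometric curve becomes uniform, i.e. every elevation
    band offers the same area.  Under uniform availability a species tracking
    an isotherm shifts its whole altitudinal distribution at exactly
    warming_rate / lapse_rate, which makes programmed shift velocities
    directly recoverable; ``hypsometry="raw"`` keeps the min-max-scaled field
    with its peaked mid-elevation area distribution.

    Parameters
    ----------
    relief : dict with keys base_elev (m), amplitude (m), n_ridges (int).
    """
    relief = {"base_elev": 400.0, "amplitude": 3400.0, "n_ridges": 4, **(relief or {})}
    if nx < 16 or ny < 16:
        raise ValueError("grid must be at least 16x16")
    if relief["amplitude"] <= 0:
        raise ValueError("relief amplitude must be positive")
    rng = np.random.default_rng(seed)
    x = (np.arange(nx) + 0.5) * cell_size
    y = (np.arange(ny) + 0.5) * cell_size
    xx, yy = np.meshgrid(x, y)
    extent = max(nx, ny) * cell_size

    ridges = np.zeros((ny, nx))
    for _ in range(int(relief["n_ridges"])):
        theta = rng.uniform(0, np.pi)
        wavelength = extent * rng.uniform(0.4, 1.2)
        phase = rng.uniform(0, 2 * np.pi)
        ridges += np.cos(
            2 * np.pi * (xx * np.cos(theta) + yy * np.sin(theta)) / wavelength + phase
        )
    noise = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma=max(2.0, nx / 16))

    def _unit(a: np.ndarray) -> np.ndarray:
        lo, hi = a.min(), a.max()
        return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)

    z = _unit(0.75 * _unit(ridges) + 0.25 * _unit(noise))
    if hypsometry == "uniform":
        from scipy.stats import rankdata

        ranks = rankdata(z.ravel(), method="average")
        z = ((ranks - 0.5) / ranks.size).reshape(z.shape)
        z = _unit(z)
    elif hypsometry != "raw":
        raise ValueError("hypsometry must be 'uniform' or 'raw'")
    values = relief["base_elev"] + relief["amplitude"] * z
    return Grid(values, cell_size=cell_size)


def make_climate_series(
    dem: Grid,
    years: list[int],
    lapse_rate: float = 0.0065,
    warming_rate: float = 0.03,
    seasonal_amp: float = 9.0,
    noise_sd: float = 0.5,
    prec_base: float = 1200.0,
    seed: int = 0,
    sea_level_temp: float = 14.0,
    diurnal_half_range: float = 4.0,
    prec_elev_gradient: float = 0.0004,
    prec_noise_frac: float = 0.1,
) -> list[MonthlyClimate]:
    """Generate a monthly climate series on the DEM geometry.

    Monthly mean temperature at a cell of elevation E in year y, month m:

        tmean = sea_level_temp + warming_rate*(y - years[0])
                - seasonal_amp*cos(2*pi*(m-1)/12) - lapse_rate*E + eps(y, m)

    with eps a spatially uniform N(0, noise_sd) interannual/monthly anomaly
    (climate fluctuations in a small region are strongly spatially coherent).
    tmin/tmax bracket tmean by ``diurnal_half_range``.  Precipitation is
    ``prec_base/12`` per month with a linear orographic increase of
    ``prec_elev_gradient`` per metre and multiplicative lognormal-ish noise,
    clipped at zero.
    """
    if lapse_rate <= 0:
        raise ValueError("lapse_rate must be positive")
    if len(years) < 1:
        raise ValueError("need at least one year")
    rng = np.random.default_rng(seed)
    E = dem.values
    months = np.arange(12)
    seasonal = -seasonal_amp * np.cos(2 * np.pi * months / 12)
    out: list[MonthlyClimate] = []
    for year in years:
        trend = warming_rate * (year - years[0])
        t_noise = rng.normal(0.0, noise_sd, size=12) if noise_sd > 0 else np.zeros(12)
        p_noise = rng.normal(0.0, prec_noise_frac, size=12) if prec_noise_frac > 0 else np.zeros(12)
        tmean = (
            sea_level_temp
            + trend
            + seasonal[:, None, None]
            + t_noise[:, None, None]
            - lapse_rate * E[None, :, :]
        )
        tmin = tmean - diurnal_half_range
        tmax = tmean + diurnal_half_range
        prec = (
            prec_base
            / 12.0
            * (1.0 + prec_elev_gradient * E[None, :, :])
            * np.clip(1.0 + p_noise[:, None, None], 0.0, None)
        )
        out.append(MonthlyClimate(year=year, tmin=tmin, tmean=tmean, tmax=tmax, prec=prec))
    return out


def make_insolation(
    dem: Grid,
    months: list[int] | None = None,
    sun_elevations: list[float] | None = None,
    azimuth_deg: float = 180.0,
    scale: float = 1000.0,
) -> dict[int, np.ndarray]:
    """Monthly insolation proxy from a fixed-azimuth hillshade.

    For each month a single sun elevation is used; the proxy is the standard
    hillshade kernel cos(zen)cos(slope) + sin(zen)sin(slope)cos(az - aspect),
    clipped at zero and rescaled to a nominal W/m^2*h range.  A stand-in for
    full solar-geometry rasters: its only role is supplying topographic axes.
    """
    if months is None:
        months = list(range(1, 13))
    if sun_elevations is None:
        # annual cycle of monthly noon sun elevation at mid-latitudes
        sun_elevations = [
            20.0, 28.0, 40.0, 52.0, 61.0, 65.0, 63.0, 55.0, 43.0, 31.0, 22.0, 18.0
        ][: len(months)]
    if len(sun_elevations) != len(months):
        raise ValueError("sun_elevations must match months in length")
    slope, aspect = slope_aspect(dem)
    az = np.deg2rad(azimuth_deg)
    out: dict[int, np.ndarray] = {}
    for month, sun_elev in zip(months, sun_elevations):
        zen = np.deg2rad(90.0 - sun_elev)
        hs = np.cos(zen) * np.cos(slope) + np.sin(zen) * np.sin(slope) * np.cos(az - aspect)
        out[int(month)] = np.clip(hs, 0.0, None) * scale
    return out


def suitability(
    spec: SpeciesSpec, annual_tmean: np.ndarray, annual_prec: np.ndarray
) -> np.ndarray:
    """Gaussian climatic suitability in (annual tmean, annual prec), in [0, 1]."""
    st = np.exp(-0.5 * ((annual_tmean - spec.thermal_optimum) / spec.thermal_breadth) ** 2)
    sp = np.exp(-0.5 * ((annual_prec - spec.prec_optimum) / spec.prec_breadth) ** 2)
    return st * sp


def sample_records(
    species: list[SpeciesSpec],
    climate: list[MonthlyClimate],
    dem: Grid,
    seed: int = 0,
    season: tuple[int, int] = (6, 8),
) -> pd.DataFrame:
    """Draw occurrence records for each species-year.

    Counts are Poisson with mean ``records_per_year * detectability``; record
    cells are drawn (with replacement) with probability proportional to the
    Gaussian climatic suitability of that year.  Coordinates are exact cell
    centres; elevation is read from the DEM; the date is a uniform random day
    within the flight season (intra-year placement is cosmetic — downstream
    statistics use only the year).
    """
    if not species:
        raise ValueError("need at least one species")
    if len(climate) < 2:
        raise ValueError("need at least two years of climate")
    rng = np.random.default_rng(seed)
    valid = np.isfinite(dem.values)
    rows_r, cols_r = np.nonzero(valid)
    elev = dem.values[rows_r, cols_r]
    season_months = [m for m in range(season[0], season[1] + 1)]
    season_days = np.concatenate(
        [np.arange(1, MONTH_DAYS[m - 1] + 1) for m in season_months]
    )
    season_month_of_day = np.concatenate(
        [np.full(MONTH_DAYS[m - 1], m) for m in season_months]
    )

    # regional annual-mean anomaly relative to the first year, used to let a
    # species with tracking < 1 tolerate part of the warming in place
    annual_means = np.array([np.nanmean(mc.annual_tmean()) for mc in climate])
    anomalies = annual_means - annual_means[0]

    records: list[tuple] = []
    for spec in species:
        for mc, anomaly in zip(climate, anomalies):
            eff = SpeciesSpec(
                name=spec.name,
                thermal_optimum=spec.thermal_optimum + (1.0 - spec.tracking) * anomaly,
                thermal_breadth=spec.thermal_breadth,
                prec_optimum=spec.prec_optimum,
                prec_breadth=spec.prec_breadth,
                detectability=spec.detectability,
                records_per_year=spec.records_per_year,
                traits=spec.traits,
                tracking=spec.tracking,
            )
            suit = suitability(eff, mc.annual_tmean(), mc.annual_prec())[rows_r, cols_r]
            n = rng.poisson(spec.records_per_year * spec.detectability)
            total = suit.sum()
            if total <= np.finfo(float).eps:
                logger.warning(
                    "species %s has no suitable area in %d; zero records", spec.name, mc.year
                )
                continue
            if n == 0:
                continue
            p = suit / total
            idx = rng.choice(suit.size, size=n, replace=True, p=p)
            day_idx = rng.integers(0, season_days.size, size=n)
            x, y = dem.cell_center(rows_r[idx], cols_r[idx])
            for k in range(n):
                date = (
                    f"{mc.year:04d}-{season_month_of_day[day_idx[k]]:02d}-"
                    f"{season_days[day_idx[k]]:02d}"
                )
                records.append((spec.name, date, x[k], y[k], elev[idx[k]]))
    df = pd.DataFrame(records, columns=["species", "date", "x", "y", "elevation"])
    df["year"] = df["date"].str.slice(0, 4).astype(int) if len(df) else pd.Series(dtype=int)
    return df


def expected_uphill_velocity(warming_rate: float, lapse_rate: float) -> float:
    """Isotherm (and thermal-niche) uphill velocity in m/yr: warming / lapse."""
    return warming_rate / lapse_rate
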