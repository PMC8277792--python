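"""Elevational shift statistics from records and from SDM surfaces.

For every species an annual altitudinal distribution (the occurrence vector
h) is built either from its raw records or from the surviving cells of its
rescaled SDM surface (elevation weighted by occurrence probability).  From
these the headline statistics are derived:

* z_alt   — OLS slope of record altitude against year (m/yr); for SDM series,
            slope of the annual probability-weighted median altitude.
* z_range — slope of annual altitudinal range size against year.
* z_VMR   — slope of the annual variance-mean ratio VMR = sigma^2(h) / mu(h),
            a variance-based index of altitudinal range size.
* z_skew  — slope of annual skewness, computed only for years with records at
            >= 5 sites of different altitude and species with >= 5 such years.

Extreme-record years (t_min, t_max), decadal median anomalies and altitudinal
richness profiles complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid
from .maxent import ProbabilitySurface


@dataclass
class AnnualStats:
    """Moments of one year's altitudinal distribution."""

    year: int
    median_alt: float
    mean_alt: float
    range_size: float
    vmr: float | None
    skewness: float | None
    n_sites: int


@dataclass
class SlopeSet:
    """Per-species shift statistics feeding the trait models."""

    species: str
    source: str                  # 'records' | 'sdm'
    z_alt: float | None
    z_range: float | None
    z_vmr: float | None
    z_skew: float | None
    t_min_year: int
    t_max_year: int
    median_alt: float
    overall_vmr: float
    overall_skew: float | None


def weighted_quantile(values, q: float, weights=None) -> float:
    """Smallest value whose cumulative normalized weight reaches q.

    With equal weights this is a lower-step empirical quantile; q = 0.5 gives
    the weighted median used for SDM surfaces.
    """
    v = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
    if v.size == 0 or w.sum() <= 0:
        raise ValueError("empty or zero-weight vector")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w) / w.sum()
    return float(v[np.searchsorted(cum, q - 1e-12)])


def weighted_median_elevation(
    surface: ProbabilitySurface, dem: Grid
) -> tuple[float, float]:
    """Probability-weighted median and mean elevation of a surface.

    Uses the surviving (finite) cells of the rescaled surface as weights over
    the DEM elevations.
    """
    ok = np.isfinite(surface.values) & np.isfinite(dem.values)
    if not ok.any():
        raise ValueError("surface has no surviving cells")
    w = surface.values[ok]
    e = dem.values[ok]
    if w.sum() <= 0:
        # all survivors at exactly the threshold: fall back to equal weights
        w = np.ones_like(w)
    med = weighted_quantile(e, 0.5, w)
    mean = float((w * e).sum() / w.sum())
    return med, mean


def _weighted_moments(h: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Weighted mean, sample variance and g1 skewness (frequency weights)."""
    sw = w.sum()
    mu = (w * h).sum() / sw
    d = h - mu
    m2 = (w * d**2).sum() / sw
    m3 = (w * d**3).sum() / sw
    n = h.size
    var = m2 * n / (n - 1) if n > 1 else 0.0
    g1 = m3 / m2**1.5 if m2 > 0 else 0.0
    return float(mu), float(var), float(g1)


def annual_stats(h, weights=None, year: int = 0) -> AnnualStats:
    """Moments of an altitudinal occurrence vector h (optionally weighted).

    VMR = sample variance / mean (sample n-1 convention; the weighted variant
    treats weights as frequencies normalized to their sum).  Skewness is the
    adjusted Fisher-Pearson g1 * sqrt(n(n-1))/(n-2) when unweighted, plain g1
    when weighted (SDM cell counts are large).  n_sites counts distinct
    elevations after rounding to 1 m.
    """
    h = np.asarray(h, dtype=float)
    if h.size == 0:
        raise ValueError("empty occurrence vector")
    n = h.size
    n_sites = int(np.unique(np.round(h)).size)
    range_size = float(h.max() - h.min())
    if weights is None:
        mu = float(h.mean())
        med = float(np.median(h))
        var = float(h.var(ddof=1)) if n > 1 else None
        if n > 2:
            g1 = stats.skew(h, bias=True) if np.ptp(h) > 0 else 0.0
            skew = float(g1 * np.sqrt(n * (n - 1)) / (n - 2))
        else:
            skew = None
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero")
        mu_w, var_w, g1 = _weighted_moments(h, w)
        mu, med = mu_w, weighted_quantile(h, 0.5, w)
        var = var_w if n > 1 else None
        skew = g1 if n > 2 else None
    vmr = None
    if var is not None:
        vmr = var / mu if mu != 0 else None
    return AnnualStats(
        year=int(year),
        median_alt=med,
        mean_alt=mu,
        range_size=range_size,
        vmr=vmr,
        skewness=skew,
        n_sites=n_sites,
    )


def slope(years, values) -> tuple[float, float, float]:
    """OLS slope, r^2 and two-sided parametric p of values against year."""
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("need at least two distinct years")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2), float(res.pvalue)


def slope_with_se(years, values) -> tuple[float, float]:
    """OLS slope and its standard error."""
    res = stats.linregress(np.asarray(years, float), np.asarray(values, float))
    return float(res.slope), float(res.stderr)


def extreme_record_years(years, elevations) -> tuple[int, int]:
    """Calendar years of the single lowest and highest occurrence.

    Ties in elevation are broken by the earliest year.
    """
    df = pd.DataFrame({"year": years, "elevation": elevations})
    if df.empty:
        raise ValueError("no records")
    lo = df.sort_values(["elevation", "year"], kind="stable").iloc[0]
    hi = df.sort_values(["elevation", "year"], ascending=[False, True], kind="stable").iloc[0]
    return int(lo["year"]), int(hi["year"])


def annual_series_from_records(records: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per-year elevation vectors for one species' records."""
    if "year" not in records.columns:
        records = records.assign(year=records["date"].str.slice(0, 4).astype(int))
    return {
        int(y): g["elevation"].to_numpy(dtype=float)
        for y, g in records.groupby("year")
    }


def annual_series_from_surfaces(
    surfaces: list[ProbabilitySurface], dem: Grid
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-year (elevation, weight) pairs from surviving SDM cells."""
    out = {}
    for s in surfaces:
        ok = np.isfinite(s.values) & np.isfinite(dem.values)
        if ok.any() and s.values[ok].sum() > 0:
            out[int(s.year)] = (dem.values[ok], s.values[ok])
    return out


def z_skew_filtered(
    series: dict[int, np.ndarray | tuple[np.ndarray, np.ndarray]],
    min_sites: int = 5,
    min_years: int = 5,
) -> float | None:
    """Slope of annual skewness vs year over qualifying years, else None.

    A year qualifies when the species occurs at >= min_sites sites of
    different altitude (distinct 1 m-rounded elevations, weight > 0 cells for
    SDM series); the slope needs >= min_years qualifying years.
    """
    years, skews = [], []
    for y in sorted(series):
        entry = series[y]
        h, w = (entry, None) if isinstance(entry, np.ndarray) else entry
        hh = h if w is None else h[np.asarray(w) > 0]
        if np.unique(np.round(hh)).size < min_sites:
            continue
        st = annual_stats(h, weights=w, year=y)
        if st.skewness is not None:
            years.append(y)
            skews.append(st.skewness)
    if len(years) < min_years:
        return None
    return slope(years, skews)[0]


def compute_slopeset(
    species: str,
    series: dict[int, np.ndarray | tuple[np.ndarray, np.ndarray]],
    source: str = "records",
    min_sites: int = 5,
    min_years: int = 5,
) -> SlopeSet:
    """All shift statistics for one species from its annual series.

    Record-based z_alt regresses every individual (year, elevation) pair;
    SDM-based z_alt regresses the annual weighted median.  Record-based
    annual range size is max - min; the SDM analogue uses the weighted
    p95 - p5 span, which is robust to single surviving cells.
    """
    years = sorted(series)
    if not years:
        raise ValueError("empty series")
    weighted = not isinstance(series[years[0]], np.ndarray)

    # pooled distribution for overall statistics and extreme years
    all_h, all_w, rec_years = [], [], []
    annual: list[AnnualStats] = []
    for y in years:
        entry = series[y]
        h, w = (entry, None) if not weighted else entry
        all_h.append(h)
        all_w.append(np.ones_like(h) if w is None else w)
        rec_years.append(np.full(h.size if w is None else np.size(h), y))
        annual.append(annual_stats(h, weights=w, year=y))
    pooled_h = np.concatenate(all_h)
    pooled_w = np.concatenate(all_w)
    pooled_y = np.concatenate(rec_years)

    if weighted:
        med_by_year = [(a.year, a.median_alt) for a in annual]
        if len(med_by_year) >= 2:
            z_alt = slope(*zip(*med_by_year))[0]
        else:
            z_alt = None
        t_min_year = min(med_by_year, key=lambda t: (t[1], t[0]))[0]
        t_max_year = max(med_by_year, key=lambda t: (t[1], -t[0]))[0]
        spans = [
            (y, weighted_quantile(h, 0.95, w) - weighted_quantile(h, 0.05, w))
            for y, (h, w) in ((yy, series[yy]) for yy in years)
        ]
    else:
        z_alt = slope(pooled_y, pooled_h)[0] if np.ptp(pooled_y) > 0 else None
        t_min_year, t_max_year = extreme_record_years(pooled_y, pooled_h)
        spans = [(a.year, a.range_size) for a in annual]

    z_range = slope(*zip(*spans))[0] if len(spans) >= 2 else None
    vmr_pairs = [(a.year, a.vmr) for a in annual if a.vmr is not None]
    z_vmr = slope(*zip(*vmr_pairs))[0] if len(vmr_pairs) >= 2 else None
    z_skew = z_skew_filtered(series, min_sites=min_sites, min_years=min_years)

    overall = annual_stats(pooled_h, weights=pooled_w if weighted else None)
    return SlopeSet(
        species=species,
        source=source,
        z_alt=z_alt,
        z_range=z_range,
        z_vmr=z_vmr,
        z_skew=z_skew,
        t_min_year=t_min_year,
        t_max_year=t_max_year,
        median_alt=overall.median_alt,
        overall_vmr=overall.vmr if overall.vmr is not None else np.nan,
        overall_skew=overall.skewness,
    )


def slopesets_to_frame(slopesets: list[SlopeSet]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species,
                "source": s.source,
                "z_alt": s.z_alt,
                "z_range": s.z_range,
                "z_vmr": s.z_vmr,
                "z_skew": s.z_skew,
                "t_min_year": s.t_min_year,
                "t_max_year": s.t_max_year,
                "median_alt": s.median_alt,
                "overall_vmr": s.overall_vmr,
                "overall_skew": s.overall_skew,
            }
            for s in slopesets
        ]
    )


def decadal_median_shift(
    series_by_species: dict[str, dict[int, np.ndarray | tuple[np.ndarray, np.ndarray]]],
    decades: list[int] | None = None,
) -> tuple[pd.DataFrame, tuple[float, float, float]]:
    """Median altitudinal anomaly per calendar decade, with an OLS trend.

    For each species, Delta(s, d) = median altitude within decade d minus the
    species' overall median; the per-decade value is the median of Delta over
    the species with data in that decade.  Returns the per-decade table and
    (slope per decade-index, r^2, p).
    """
    all_years = sorted({y for s in series_by_species.values() for y in s})
    if decades is None:
        decades = sorted({(y // 10) * 10 for y in all_years})
    rows = []
    for sp, series in series_by_species.items():
        pooled_h, pooled_w = [], []
        for y in series:
            entry = series[y]
            h, w = (entry, None) if isinstance(entry, np.ndarray) else entry
            pooled_h.append(h)
            pooled_w.append(np.ones_like(h) if w is None else w)
        overall = weighted_quantile(np.concatenate(pooled_h), 0.5, np.concatenate(pooled_w))
        for dec in decades:
            hh, ww = [], []
            for y in series:
                if (y // 10) * 10 == dec:
                    entry = series[y]
                    h, w = (entry, None) if isinstance(entry, np.ndarray) else entry
                    hh.append(h)
                    ww.append(np.ones_like(h) if w is None else w)
            if not hh:
                continue
            med = weighted_quantile(np.concatenate(hh), 0.5, np.concatenate(ww))
            rows.append({"species": sp, "decade": dec, "anomaly": med - overall})
    per_species = pd.DataFrame(rows)
    per_decade = (
        per_species.groupby("decade")["anomaly"].median().reset_index()
        if len(per_species)
        else pd.DataFrame(columns=["decade", "anomaly"])
    )
    if len(per_decade) >= 2:
        idx = (per_decade["decade"] - per_decade["decade"].min()) // 10
        fit = slope(idx, per_decade["anomaly"])
    else:
        fit = (float("nan"),) * 3
    return per_decade, fit


def richness_profile(
    surfaces_by_species: dict[str, ProbabilitySurface],
    dem: Grid,
    bin_edges: np.ndarray,
) -> np.ndarray:
    """Expected species richness per altitude bin for one year.

    Per bin, the mean rescaled probability over the bin's cells is summed
    across species (nodata cells count as probability 0).
    """
    edges = np.asarray(bin_edges, dtype=float)
    elev = dem.values.ravel()
    ok = np.isfinite(elev)
    which = np.digitize(elev[ok], edges) - 1
    n_bins = edges.size - 1
    profile = np.zeros(n_bins)
    for surface in surfaces_by_species.values():
        p = np.nan_to_num(surface.values.ravel()[ok], nan=0.0)
        for b in range(n_bins):
            sel = which == b
            if sel.any():
                profile[b] += p[sel].mean()
    return profile


def profile_centroid(profile: np.ndarray, bin_edges: np.ndarray) -> float:
    """Probability-weighted mean altitude of a richness profile."""
    mids = (np.asarray(bin_edges[:-1]) + np.asarray(bin_edges[1:])) / 2.0
    tot = profile.sum()
    if tot <= 0:
        raise ValueError("empty profile")
    return float((profile * mids).sum() / tot)
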