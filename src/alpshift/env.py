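"""Environmental layers: bioclimatic variables, downscaling, PCA, SWD tables.

Annual bioclimatic variables are derived from the 12 monthly temperature and
precipitation grids using the standard bio1-bio19 definitions (quarters are
rolling three-month windows with December-January wraparound).  Dimensionality
is reduced with two separate PCAs — one over the bioclimatic variables, one
over the monthly insolation layers — retaining components with eigenvalue > 1
(Kaiser rule).  Species-with-data (SWD) tables pair each presence or
background point with the PCA scores of its own record year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Grid
from .synthetic import MonthlyClimate

logger = logging.getLogger(__name__)

#: Default retained bioclim set: the quarter-hybrid variables bio8/bio9/bio18/
#: bio19 (temperature of wettest/driest quarter, precipitation of warmest/
#: coldest quarter) are excluded as artifact-prone.
DEFAULT_BIOCLIM = (
    "bio1", "bio2", "bio3", "bio4", "bio5", "bio6", "bio7",
    "bio10", "bio11", "bio12", "bio13", "bio14", "bio15", "bio16", "bio17",
)

BACKGROUND_LABEL = "background"


@dataclass
class BioclimGrid:
    """Named annual bioclim layers for one year, on the working geometry."""

    year: int
    layers: dict[str, np.ndarray]

    def stack(self, names: list[str] | None = None) -> np.ndarray:
        names = list(names or self.layers)
        return np.stack([self.layers[n] for n in names])


def _quarter_windows(monthly: np.ndarray) -> np.ndarray:
    """Rolling 3-month sums with wraparound; shape (12, ...)."""
    return np.stack(
        [monthly[i] + monthly[(i + 1) % 12] + monthly[(i + 2) % 12] for i in range(12)]
    )


def compute_bioclim(mc: MonthlyClimate, variable_set=DEFAULT_BIOCLIM) -> BioclimGrid:
    """Compute annual bioclimatic variables from monthly climate.

    Standard definitions: bio1 = annual mean of monthly tmean, bio4 = 100 x
    s.d. of monthly tmean, bio5/bio6 = extreme monthly tmax/tmin, bio12 =
    annual precipitation sum, bio15 = 100 x s.d./(mean + 1) of monthly
    precipitation (the +1 guards arid cells), quarters = consecutive 3-month
    windows with wraparound, warmest/wettest quarter chosen per cell.
    """
    tmean, tmin, tmax, prec = mc.tmean, mc.tmin, mc.tmax, mc.prec
    if tmean.shape[0] != 12:
        raise ValueError("12 monthly layers required")
    q_tmean = _quarter_windows(tmean) / 3.0
    q_prec = _quarter_windows(prec)

    def _pick(stack: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(stack, idx[None], axis=0)[0]

    wettest = np.argmax(q_prec, axis=0)
    driest = np.argmin(q_prec, axis=0)
    warmest = np.argmax(q_tmean, axis=0)
    coldest = np.argmin(q_tmean, axis=0)

    layers: dict[str, np.ndarray] = {}
    layers["bio1"] = tmean.mean(axis=0)
    layers["bio2"] = (tmax - tmin).mean(axis=0)
    layers["bio5"] = tmax.max(axis=0)
    layers["bio6"] = tmin.min(axis=0)
    layers["bio7"] = layers["bio5"] - layers["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        layers["bio3"] = np.where(
            layers["bio7"] != 0, 100.0 * layers["bio2"] / layers["bio7"], 0.0
        )
    layers["bio4"] = 100.0 * tmean.std(axis=0, ddof=1)
    layers["bio8"] = _pick(q_tmean, wettest)
    layers["bio9"] = _pick(q_tmean, driest)
    layers["bio10"] = _pick(q_tmean, warmest)
    layers["bio11"] = _pick(q_tmean, coldest)
    layers["bio12"] = prec.sum(axis=0)
    layers["bio13"] = prec.max(axis=0)
    layers["bio14"] = prec.min(axis=0)
    layers["bio15"] = 100.0 * prec.std(axis=0, ddof=1) / (prec.mean(axis=0) + 1.0)
    layers["bio16"] = _pick(q_prec, wettest)
    layers["bio17"] = _pick(q_prec, driest)
    layers["bio18"] = _pick(q_prec, warmest)
    layers["bio19"] = _pick(q_prec, coldest)

    unknown = set(variable_set) - set(layers)
    if unknown:
        raise ValueError(f"unknown bioclim variables: {sorted(unknown)}")
    return BioclimGrid(year=mc.year, layers={k: layers[k] for k in variable_set})


def gwr_downscale(
    coarse_temp: Grid,
    coarse_dem: Grid,
    fine_dem: Grid,
    bandwidth: float | None = None,
    cutoff_factor: float = 4.0,
) -> Grid:
    """Downscale a coarse temperature grid by geographically weighted regression.

    For every fine cell a weighted least-squares fit of temperature on
    elevation over the coarse cells (Gaussian kernel exp(-d^2 / 2 bw^2) on
    centre-to-centre distance, truncated at ``cutoff_factor`` bandwidths) is
    evaluated at the fine cell's elevation.  Fine cells with fewer than 3
    positive-weight coarse neighbours become nodata; a locally constant
    elevation design falls back to the weighted mean.
    """
    if bandwidth is None:
        bandwidth = 3.0 * coarse_dem.cell_size
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if coarse_temp.shape != coarse_dem.shape:
        raise ValueError("coarse grids must share geometry")
    cx = coarse_dem.x_coords()
    cy = coarse_dem.y_coords()
    cxx, cyy = np.meshgrid(cx, cy)
    valid = np.isfinite(coarse_temp.values) & np.isfinite(coarse_dem.values)
    cxf, cyf = cxx[valid], cyy[valid]
    te, el = coarse_temp.values[valid], coarse_dem.values[valid]

    out = np.full(fine_dem.shape, np.nan)
    fx = fine_dem.x_coords()
    fy = fine_dem.y_coords()
    cutoff2 = (cutoff_factor * bandwidth) ** 2
    n_fallback = 0
    for i in range(fine_dem.ny):
        d2y = (cyf - fy[i]) ** 2
        for j in range(fine_dem.nx):
            ef = fine_dem.values[i, j]
            if not np.isfinite(ef):
                continue
            d2 = (cxf - fx[j]) ** 2 + d2y
            near = d2 <= cutoff2
            if near.sum() < 3:
                continue
            w = np.exp(-d2[near] / (2.0 * bandwidth**2))
            e, t = el[near], te[near]
            sw = w.sum()
            ebar = (w * e).sum() / sw
            tbar = (w * t).sum() / sw
            sxx = (w * (e - ebar) ** 2).sum()
            if sxx <= 1e-12 * sw:
                out[i, j] = tbar
                n_fallback += 1
                continue
            beta = (w * (e - ebar) * (t - tbar)).sum() / sxx
            out[i, j] = tbar + beta * (ef - ebar)
    if n_fallback:
        logger.info("gwr_downscale: weighted-mean fallback at %d cells", n_fallback)
    return fine_dem.like(out)


def bilinear_downscale(coarse: Grid, fine_like: Grid) -> Grid:
    """Bilinear interpolation of a coarse grid onto a fine geometry.

    Interpolates between coarse cell centres; fine cells beyond the outermost
    centres are clamped to the edge value.
    """
    x0c, y0c = coarse.origin
    fi = (fine_like.y_coords() - y0c) / coarse.cell_size - 0.5
    fj = (fine_like.x_coords() - x0c) / coarse.cell_size - 0.5
    jj, ii = np.meshgrid(fj, fi)
    vals = ndimage.map_coordinates(
        coarse.values, [ii.ravel(), jj.ravel()], order=1, mode="nearest"
    ).reshape(fine_like.shape)
    return fine_like.like(vals)


@dataclass
class PCASpace:
    """A fitted z-score PCA: standardisation constants, loadings, eigenvalues."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray       # variables x components, orthonormal columns
    eigenvalues: np.ndarray    # non-increasing, sample (n-1) convention
    n_retained: int


def fit_env_pca(X, columns: list[str] | None = None) -> PCASpace:
    """Fit a PCA on z-scored variables, retaining eigenvalues > 1.

    Zero-variance variables are dropped with a warning before decomposition.
    Eigenvalues use the sample (n-1) covariance convention, so they sum to the
    number of retained input variables.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least 2 variables")
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need at least variables + 1 observations")
    if columns is None:
        columns = [f"v{i}" for i in range(X.shape[1])]
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        warnings.warn(f"dropping zero-variance variables: {dropped}")
        X = X[:, keep]
        columns = [c for c, k in zip(columns, keep) if k]
        sds = sds[keep]
    means = X.mean(axis=0)
    Z = (X - means) / sds
    # SVD of the centred z-scores; eigenvalues of the sample correlation matrix
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (Z.shape[0] - 1)
    n_retained = max(int((eig > 1.0).sum()), 1)
    return PCASpace(
        columns=list(columns),
        means=means,
        sds=sds,
        loadings=vt.T,
        eigenvalues=eig,
        n_retained=n_retained,
    )


def project_pca(space: PCASpace, X, n_components: int | None = None) -> np.ndarray:
    """Project observations into the retained principal components."""
    X = np.asarray(X, dtype=float)
    k = space.n_retained if n_components is None else n_components
    Z = (X - space.means) / space.sds
    return Z @ space.loadings[:, :k]


def insolation_matrix(insol: dict[int, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    """Flatten monthly insolation grids to a (cells x months) matrix."""
    months = sorted(insol)
    mat = np.stack([insol[m].ravel() for m in months], axis=1)
    return mat, [f"insol{m:02d}" for m in months]


def pca_score_grids(
    bio: BioclimGrid, space: PCASpace, shape: tuple[int, int]
) -> np.ndarray:
    """Per-cell climate PCA scores for one year; shape (n_retained, ny, nx)."""
    mat = np.stack([bio.layers[c].ravel() for c in space.columns], axis=1)
    scores = project_pca(space, mat)
    return scores.T.reshape(space.n_retained, *shape)


def extract_swd(
    records: pd.DataFrame,
    bioclim_by_year: dict[int, BioclimGrid],
    climate_pca: PCASpace,
    grid: Grid,
    insol: dict[int, np.ndarray] | None = None,
    topo_pca: PCASpace | None = None,
) -> pd.DataFrame:
    """Build an SWD table: one row per record with year-matched PCA scores.

    Environmental values are taken from the record's own year of discovery.
    Records outside the grid or on nodata cells are dropped (count logged).
    """
    if "year" not in records.columns:
        records = records.assign(year=records["date"].str.slice(0, 4).astype(int))
    missing_years = set(records["year"]) - set(bioclim_by_year)
    if missing_years:
        raise ValueError(f"no climate layers for years: {sorted(missing_years)}")

    row, col = grid.cell_index(records["x"].to_numpy(), records["y"].to_numpy())
    inside = (row >= 0) & (col >= 0)
    n_dropped = int((~inside).sum())

    pc_names = [f"pc{i+1}" for i in range(climate_pca.n_retained)]
    topo_scores = None
    topo_names: list[str] = []
    if insol is not None and topo_pca is not None:
        mat, _ = insolation_matrix(insol)
        topo_scores = project_pca(topo_pca, mat).reshape(
            grid.ny, grid.nx, topo_pca.n_retained
        )
        topo_names = [f"topo{i+1}" for i in range(topo_pca.n_retained)]

    out_rows: list[list] = []
    flat = row * grid.nx + col
    for year, bio in bioclim_by_year.items():
        sel = inside & (records["year"].to_numpy() == year)
        if not sel.any():
            continue
        mat = np.stack([bio.layers[c].ravel() for c in climate_pca.columns], axis=1)
        env = mat[flat[sel]]
        good = np.isfinite(env).all(axis=1)
        n_dropped += int((~good).sum())
        scores = project_pca(climate_pca, env[good])
        idx = np.nonzero(sel)[0][good]
        for k, i in enumerate(idx):
            rec = records.iloc[i]
            vals = [rec["species"], rec["x"], rec["y"], year, *scores[k]]
            if topo_scores is not None:
                vals.extend(topo_scores[row[i], col[i]])
            out_rows.append(vals)
    if n_dropped:
        logger.info("extract_swd: dropped %d records outside grid or on nodata", n_dropped)
    cols = ["species", "x", "y", "year", *pc_names, *topo_names]
    df = pd.DataFrame(out_rows, columns=cols)
    return df.sort_values(["species", "year"], kind="stable").reset_index(drop=True)


def sample_background(
    years: list[int],
    n_per_year: int,
    grid: Grid,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform random background points, resampled independently per year.

    Sampling is without replacement within a year over the grid's finite
    cells; coordinates are cell centres, the species label is the literal
    string ``background``.
    """
    rng = np.random.default_rng(seed)
    rows_r, cols_r = np.nonzero(np.isfinite(grid.values))
    if n_per_year > rows_r.size:
        raise ValueError("n_per_year exceeds number of valid cells")
    frames = []
    for year in years:
        idx = rng.choice(rows_r.size, size=n_per_year, replace=False)
        x, y = grid.cell_center(rows_r[idx], cols_r[idx])
        frames.append(
            pd.DataFrame(
                {
                    "species": BACKGROUND_LABEL,
                    "x": x,
                    "y": y,
                    "year": year,
                    "elevation": grid.values[rows_r[idx], cols_r[idx]],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
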