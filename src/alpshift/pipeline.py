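"""End-to-end pipeline: simulate -> env -> sdm -> niche -> shift -> traits.

Every stage reads and writes only files under the output directory, so each
stage is independently runnable and resumable; a manifest records the config
hash and per-stage status.  Identical config and seeds give byte-identical
result CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import env as envmod
from . import maxent as mx
from . import niche as nichemod
from . import shifts as shiftmod
from . import synthetic as syn
from . import traits as traitmod
from .grids import Grid, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

STAGES = ("simulate", "env", "sdm", "niche", "shift", "traits", "report")

# programmed niche-tracking fractions and thermal breadths per trait level;
# these give mobile species a larger realized uphill velocity than sedentary
# ones and generalists a broader climatic niche than specialists
TRACKING_BY_DISPERSAL = {"sedentary": 0.4, "intermediate": 0.7, "mobile": 1.0}
BREADTH_BY_EURYOCY = {"generalist": 1.2, "specialist": 0.6}


@dataclass
class PipelineConfig:
    """Full study configuration with the defaults of the synthetic study."""

    nx: int = 100
    ny: int = 100
    cell_size: float = 100.0
    relief: dict = field(
        default_factory=lambda: {"base_elev": 400.0, "amplitude": 3400.0, "n_ridges": 4}
    )
    year_start: int = 1961
    year_end: int = 2019
    n_species: int = 15
    records_per_year: float = 10.0
    lapse_rate: float = 0.0065
    warming_rate: float = 0.03
    seasonal_amp: float = 9.0
    noise_sd: float = 0.5
    prec_base: float = 1200.0
    sea_level_temp: float = 14.0
    beta: float = 1.0
    replicates: int = 100
    train_frac: float = 0.8
    omission_rate: float = 0.10
    background_per_year: int = 1000
    nu: float = 0.05
    gamma: float | None = None
    n_mc: int = 20000
    min_records: int = 13
    low_elev_threshold: float = 600.0
    max_low_elev_fraction: float = 0.05
    min_sites: int = 5
    min_years: int = 5
    seed: int = 1

    @property
    def years(self) -> list[int]:
        if self.year_end < self.year_start:
            raise ValueError("years must be ascending")
        return list(range(self.year_start, self.year_end + 1))

    def stage_seed(self, stage: str) -> int:
        """A per-stage seed derived from the master seed (kept below 2^31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def default_species(cfg: PipelineConfig, seed: int) -> list[syn.SpeciesSpec]:
    """Random virtual species with trait-programmed niches.

    Thermal optima are spread over the mid-elevation belt of the gradient;
    dispersal sets the niche-tracking fraction, euryocy the thermal breadth,
    endangerment is assigned independently.
    """
    rng = np.random.default_rng(seed)
    dem_span = cfg.relief["amplitude"]
    base = cfg.relief["base_elev"]
    species = []
    dispersal_levels = list(TRACKING_BY_DISPERSAL)
    euryocy_levels = list(BREADTH_BY_EURYOCY)
    for i in range(cfg.n_species):
        # optimum elevation in the central 20-80% of the gradient
        opt_elev = base + dem_span * rng.uniform(0.2, 0.8)
        dispersal = dispersal_levels[i % 3]
        euryocy = euryocy_levels[(i // 3) % 2]
        endangerment = ("threatened", "least_concern")[int(rng.random() < 0.5)]
        traits = syn.SpeciesTraits(
            euryocy=euryocy, dispersal=dispersal, endangerment=endangerment
        )
        species.append(
            syn.SpeciesSpec(
                name=f"sp{i:02d}",
                thermal_optimum=cfg.sea_level_temp - cfg.lapse_rate * opt_elev,
                thermal_breadth=BREADTH_BY_EURYOCY[euryocy],
                prec_optimum=cfg.prec_base * (1.0 + 0.0004 * opt_elev),
                prec_breadth=cfg.prec_base * 0.6,
                detectability=float(rng.uniform(0.7, 1.0)),
                records_per_year=cfg.records_per_year,
                traits=traits,
                tracking=TRACKING_BY_DISPERSAL[dispersal],
            )
        )
    return species


def filter_species(
    records: pd.DataFrame,
    min_records: int = 13,
    max_low_elev_fraction: float = 0.05,
    low_elev_threshold: float = 600.0,
) -> tuple[pd.DataFrame, dict]:
    """Keep mountain species with enough data.

    Species are dropped when they have fewer than ``min_records`` records or
    when more than ``max_low_elev_fraction`` of their records lie below the
    low-elevation threshold (i.e. lowland occurrences are more than
    exceptional).  Returns the filtered table and an exclusion report.
    """
    report = {"n_input_species": int(records["species"].nunique()), "too_few_records": [],
              "too_lowland": []}
    keep = []
    for sp, g in records.groupby("species"):
        if len(g) < min_records:
            report["too_few_records"].append(sp)
            continue
        frac_low = float((g["elevation"] < low_elev_threshold).mean())
        if frac_low > max_low_elev_fraction:
            report["too_lowland"].append(sp)
            continue
        keep.append(sp)
    out = records[records["species"].isin(keep)].reset_index(drop=True)
    report["n_retained_species"] = len(keep)
    report["n_retained_records"] = int(len(out))
    return out, report


# ---------------------------------------------------------------------------
# stages


def _species_frame(species: list[syn.SpeciesSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.name,
                "thermal_optimum": s.thermal_optimum,
                "thermal_breadth": s.thermal_breadth,
                "prec_optimum": s.prec_optimum,
                "prec_breadth": s.prec_breadth,
                "detectability": s.detectability,
                "records_per_year": s.records_per_year,
                "tracking": s.tracking,
                "euryocy": s.traits.euryocy,
                "dispersal": s.traits.dispersal,
                "endangerment": s.traits.endangerment,
            }
            for s in species
        ]
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    dem = syn.make_dem(cfg.nx, cfg.ny, cfg.cell_size, cfg.relief, seed=cfg.stage_seed("dem"))
    climate = syn.make_climate_series(
        dem,
        cfg.years,
        lapse_rate=cfg.lapse_rate,
        warming_rate=cfg.warming_rate,
        seasonal_amp=cfg.seasonal_amp,
        noise_sd=cfg.noise_sd,
        prec_base=cfg.prec_base,
        sea_level_temp=cfg.sea_level_temp,
        seed=cfg.stage_seed("climate"),
    )
    insol = syn.make_insolation(dem)
    species = default_species(cfg, cfg.stage_seed("species"))
    records = syn.sample_records(species, climate, dem, seed=cfg.stage_seed("records"))

    write_ascii_grid(outdir / "dem.asc", dem)
    arrays = {}
    for mc in climate:
        for name in ("tmin", "tmean", "tmax", "prec"):
            arrays[f"{name}_{mc.year}"] = getattr(mc, name)
    np.savez_compressed(outdir / "climate.npz", **arrays)
    np.savez_compressed(
        outdir / "insolation.npz", **{f"month_{m:02d}": g for m, g in insol.items()}
    )
    _species_frame(species).to_csv(outdir / "species.csv", index=False)
    records.to_csv(outdir / "records.csv", index=False)
    return [outdir / p for p in ("dem.asc", "climate.npz", "insolation.npz",
                                 "species.csv", "records.csv")]


def load_climate(path, years: list[int]) -> list[syn.MonthlyClimate]:
    with np.load(path) as z:
        return [
            syn.MonthlyClimate(
                year=y,
                tmin=z[f"tmin_{y}"],
                tmean=z[f"tmean_{y}"],
                tmax=z[f"tmax_{y}"],
                prec=z[f"prec_{y}"],
            )
            for y in years
        ]


def stage_env(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    dem = read_ascii_grid(outdir / "dem.asc")
    climate = load_climate(outdir / "climate.npz", cfg.years)
    with np.load(outdir / "insolation.npz") as z:
        insol = {int(k.split("_")[1]): z[k] for k in z.files}
    records = pd.read_csv(outdir / "records.csv")
    records, report = filter_species(
        records, cfg.min_records, cfg.max_low_elev_fraction, cfg.low_elev_threshold
    )
    records.to_csv(outdir / "records_filtered.csv", index=False)
    (outdir / "filter_report.json").write_text(json.dumps(report, indent=2))

    bioclim_by_year = {mc.year: envmod.compute_bioclim(mc) for mc in climate}

    # climate PCA trained on year-matched bioclim values at the records
    row, col = dem.cell_index(records["x"].to_numpy(), records["y"].to_numpy())
    flat = row * dem.nx + col
    years_arr = records["year"].to_numpy()
    train = []
    for y, bio in bioclim_by_year.items():
        sel = years_arr == y
        if sel.any():
            mat = bio.stack(list(envmod.DEFAULT_BIOCLIM)).reshape(len(envmod.DEFAULT_BIOCLIM), -1).T
            train.append(mat[flat[sel]])
    climate_pca = envmod.fit_env_pca(np.vstack(train), list(envmod.DEFAULT_BIOCLIM))

    insol_mat, insol_cols = envmod.insolation_matrix(insol)
    topo_pca = envmod.fit_env_pca(insol_mat, insol_cols)

    swd_pres = envmod.extract_swd(
        records, bioclim_by_year, climate_pca, dem, insol, topo_pca
    )
    background = envmod.sample_background(
        cfg.years, cfg.background_per_year, dem, seed=cfg.stage_seed("background")
    )
    swd_bg = envmod.extract_swd(
        background, bioclim_by_year.copy(), climate_pca, dem, insol, topo_pca
    )
    # background rows need a date-free label; extract_swd preserves species col
    swd = pd.concat([swd_pres, swd_bg], ignore_index=True)
    swd.to_csv(outdir / "swd.csv", index=False)

    # per-year full-grid PCA score stacks, climate PCs + static topo PCs
    topo_scores = envmod.project_pca(topo_pca, insol_mat).T.reshape(
        topo_pca.n_retained, dem.ny, dem.nx
    )
    grids = {}
    for y, bio in bioclim_by_year.items():
        clim_scores = envmod.pca_score_grids(bio, climate_pca, dem.shape)
        grids[f"scores_{y}"] = np.concatenate([clim_scores, topo_scores], axis=0)
    np.savez_compressed(outdir / "score_grids.npz", **grids)
    pca_meta = {
        "n_climate_pcs": climate_pca.n_retained,
        "n_topo_pcs": topo_pca.n_retained,
        "climate_eigenvalues": climate_pca.eigenvalues.tolist(),
        "topo_eigenvalues": topo_pca.eigenvalues.tolist(),
        "climate_explained_frac": (
            climate_pca.eigenvalues / climate_pca.eigenvalues.sum()
        ).tolist(),
    }
    (outdir / "pca.json").write_text(json.dumps(pca_meta, indent=2))
    return [outdir / p for p in ("swd.csv", "score_grids.npz", "pca.json",
                                 "records_filtered.csv")]


def _axis_columns(swd: pd.DataFrame) -> list[str]:
    return [c for c in swd.columns if c.startswith(("pc", "topo"))]


def stage_sdm(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    dem = read_ascii_grid(outdir / "dem.asc")
    swd = pd.read_csv(outdir / "swd.csv")
    axes = _axis_columns(swd)
    bg = swd[swd["species"] == envmod.BACKGROUND_LABEL]
    bg_env = bg[axes].to_numpy()
    with np.load(outdir / "score_grids.npz") as z:
        score_grids = {int(k.split("_")[1]): z[k] for k in z.files}

    fm = mx.build_features(bg_env, axes=axes)
    models_dir = outdir / "models"
    models_dir.mkdir(exist_ok=True)
    eval_rows, series_rows = [], []
    surfaces_arrays = {}
    rng_seed = cfg.stage_seed("sdm")
    species_names = sorted(s for s in swd["species"].unique() if s != envmod.BACKGROUND_LABEL)
    for si, sp in enumerate(species_names):
        pres_env = swd.loc[swd["species"] == sp, axes].to_numpy()
        ev = mx.bootstrap_evaluate(
            pres_env,
            bg_env,
            fm,
            beta=cfg.beta,
            n_rep=cfg.replicates,
            train_frac=cfg.train_frac,
            omission_rate=cfg.omission_rate,
            seed=(rng_seed + si) % (2**31),
        )
        model = mx.fit_maxent(pres_env, bg_env, fm, beta=cfg.beta)
        (models_dir / f"{sp}.json").write_text(model.to_json())
        eval_rows.append(
            {
                "species": sp,
                "n_records": len(pres_env),
                "auc_training_mean": ev.auc_training.mean(),
                "auc_test_mean": ev.auc_test.mean() if ev.auc_test.size else np.nan,
                "omission_threshold": ev.omission_threshold_mean,
                "converged": model.converged,
            }
        )
        surfaces = mx.annual_projection(model, score_grids, ev.omission_threshold_mean)
        for s in surfaces:
            surfaces_arrays[f"{sp}_{s.year}"] = s.values.astype(np.float32)
            try:
                med, mean = shiftmod.weighted_median_elevation(s, dem)
            except ValueError:
                continue
            series_rows.append(
                {"species": sp, "year": s.year, "weighted_median": med,
                 "weighted_mean": mean}
            )
    pd.DataFrame(eval_rows).to_csv(outdir / "sdm_eval.csv", index=False)
    pd.DataFrame(series_rows).to_csv(outdir / "sdm_series.csv", index=False)
    np.savez_compressed(outdir / "surfaces.npz", **surfaces_arrays)
    return [outdir / p for p in ("sdm_eval.csv", "sdm_series.csv", "surfaces.npz")]


def stage_niche(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    swd = pd.read_csv(outdir / "swd.csv")
    axes = _axis_columns(swd)
    clim_axes = [c for c in axes if c.startswith("pc")]
    rows = []
    seed = cfg.stage_seed("niche")
    for sp, g in swd[swd["species"] != envmod.BACKGROUND_LABEL].groupby("species"):
        if len(g) < 5:
            continue
        rec = {"species": sp, "n_records": len(g)}
        for label, cols in (("climate", clim_axes), ("climate_topo", axes)):
            model = nichemod.fit_hypervolume(
                g[cols].to_numpy(), nu=cfg.nu, gamma=cfg.gamma, seed=seed
            )
            vol, se = nichemod.estimate_volume(model, n_mc=cfg.n_mc, seed=seed)
            rec[f"volume_{label}"] = vol
            rec[f"volume_{label}_se"] = se
        rows.append(rec)
    pd.DataFrame(rows).to_csv(outdir / "niche_volumes.csv", index=False)
    return [outdir / "niche_volumes.csv"]


def stage_shift(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    dem = read_ascii_grid(outdir / "dem.asc")
    records = pd.read_csv(outdir / "records_filtered.csv")
    slopesets = []
    rec_series_by_species = {}
    for sp, g in records.groupby("species"):
        series = shiftmod.annual_series_from_records(g)
        rec_series_by_species[sp] = series
        slopesets.append(
            shiftmod.compute_slopeset(
                sp, series, "records", cfg.min_sites, cfg.min_years
            )
        )
    sdm_series_by_species = {}
    with np.load(outdir / "surfaces.npz") as z:
        keys = sorted(z.files)
        by_sp: dict[str, list[mx.ProbabilitySurface]] = {}
        for k in keys:
            sp, year = k.rsplit("_", 1)
            by_sp.setdefault(sp, []).append(
                mx.ProbabilitySurface(int(year), z[k].astype(float), np.nan)
            )
    for sp, surfaces in by_sp.items():
        series = shiftmod.annual_series_from_surfaces(surfaces, dem)
        if not series:
            continue
        sdm_series_by_species[sp] = series
        slopesets.append(
            shiftmod.compute_slopeset(sp, series, "sdm", cfg.min_sites, cfg.min_years)
        )
    shiftmod.slopesets_to_frame(slopesets).to_csv(outdir / "slopes.csv", index=False)

    dec_rows = []
    for label, series_map in (("records", rec_series_by_species),
                              ("sdm", sdm_series_by_species)):
        if not series_map:
            continue
        per_decade, fit = shiftmod.decadal_median_shift(series_map)
        per_decade["source"] = label
        per_decade["trend_slope_per_decade"] = fit[0]
        per_decade["trend_r2"] = fit[1]
        per_decade["trend_p"] = fit[2]
        dec_rows.append(per_decade)
    pd.concat(dec_rows, ignore_index=True).to_csv(outdir / "decadal.csv", index=False)
    return [outdir / "slopes.csv", outdir / "decadal.csv"]


def stage_traits(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    slopes = pd.read_csv(outdir / "slopes.csv")
    species = pd.read_csv(outdir / "species.csv")
    rec = slopes[slopes["source"] == "records"].merge(
        species[["species", "euryocy", "dispersal", "endangerment"]], on="species"
    )
    results = []
    for response in ("median_alt", "z_alt", "z_range", "z_vmr", "z_skew"):
        covariate = "median_alt" if response != "median_alt" else None
        try:
            res = traitmod.fit_trait_glm(rec, response, covariate=covariate)
        except ValueError as exc:
            logger.warning("trait GLM for %s skipped: %s", response, exc)
            continue
        results.append(res)
    table = traitmod.trait_table(results)
    table.to_csv(outdir / "trait_glm.csv")
    return [outdir / "trait_glm.csv"]


def stage_report(cfg: PipelineConfig, outdir: Path) -> list[Path]:
    slopes = pd.read_csv(outdir / "slopes.csv")
    evals = pd.read_csv(outdir / "sdm_eval.csv")
    niche = pd.read_csv(outdir / "niche_volumes.csv")
    decadal = pd.read_csv(outdir / "decadal.csv")
    summary: dict = {"config_hash": cfg.config_hash()}
    for source, g in slopes.groupby("source"):
        summary[source] = {
            "n_species": int(len(g)),
            "n_tmax_after_tmin": int((g["t_max_year"] > g["t_min_year"]).sum()),
            "mean_z_alt": float(g["z_alt"].mean()),
            "frac_z_alt_positive": float((g["z_alt"] > 0).mean()),
        }
    summary["auc_training_range"] = [
        float(evals["auc_training_mean"].min()), float(evals["auc_training_mean"].max())
    ]
    summary["auc_test_range"] = [
        float(evals["auc_test_mean"].min()), float(evals["auc_test_mean"].max())
    ]
    summary["niche_climate"] = nichemod.niche_summary(niche["volume_climate"])
    for source, g in decadal.groupby("source"):
        summary.setdefault(source, {})["decadal_trend_r2"] = float(g["trend_r2"].iloc[0])
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return [outdir / "summary.json"]


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "env": stage_env,
    "sdm": stage_sdm,
    "niche": stage_niche,
    "shift": stage_shift,
    "traits": stage_traits,
    "report": stage_report,
}

STAGE_OUTPUTS = {
    "simulate": ("records.csv",),
    "env": ("swd.csv",),
    "sdm": ("sdm_series.csv",),
    "niche": ("niche_volumes.csv",),
    "shift": ("slopes.csv",),
    "traits": ("trait_glm.csv",),
    "report": ("summary.json",),
}


def run_pipeline(
    cfg: PipelineConfig,
    outdir,
    stages: tuple[str, ...] = STAGES,
    force: bool = False,
) -> dict:
    """Run pipeline stages in order, skipping stages whose outputs exist.

    Returns the run manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest = {"config_hash": cfg.config_hash(), "stages": {}}
    for stage in STAGES:
        if stage not in stages:
            continue
        markers = [outdir / f for f in STAGE_OUTPUTS[stage]]
        if not force and all(m.exists() for m in markers):
            manifest["stages"][stage] = {"status": "cached",
                                         "outputs": [str(m) for m in markers]}
            continue
        t0 = time.time()
        try:
            outputs = STAGE_FUNCS[stage](cfg, outdir)
        except FileNotFoundError as exc:
            raise RuntimeError(
                f"stage {stage!r} failed: missing upstream output ({exc})"
            ) from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 2),
            "outputs": [str(p) for p in outputs],
        }
        logger.info("stage %s done in %.1fs", stage, time.time() - t0)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
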