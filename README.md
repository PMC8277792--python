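# alpshift

Altitudinal range-shift analysis for mountain species from long-term
occurrence records and annual climate grids.

Museum and survey records of mountain butterflies (and similar taxa) span
decades but are sparse, unstandardised, and fluctuate with detectability.
`alpshift` implements the twin-track analysis used to extract robust
elevational trends from such data: the raw records on one side, and annual
species distribution models (SDMs) on the other, so that sampling noise in
the records and reconstruction error in the climate layers can be checked
against each other. A synthetic-data generator builds mountain landscapes,
warming climates and virtual species with *known* niches and shift rates, so
every stage of the pipeline is verifiable by parameter recovery — no
external data download is needed.

## What it computes

For each species and each study year an altitudinal occurrence vector *h* is
built from the records (or from the surviving cells of the SDM surface,
elevation weighted by occurrence probability). From these:

- **z_alt** — OLS slope of record altitude on year (m/yr); for SDMs, the slope
  of the annual probability-weighted median altitude,
- **z_range** — slope of annual altitudinal range size on year,
- **z_VMR** — slope of the annual variance–mean ratio, VMR = σ²(h)/μ(h),
- **z_skew** — slope of annual skewness, restricted to years with records at
  ≥ 5 sites of different altitude and species with ≥ 5 such years,
- extreme-record years (t_min, t_max), decadal median anomalies, and
  altitudinal species-richness profiles.

The SDM is a from-scratch maximum-entropy presence–background model
(linear, quadratic and product features scaled to [0, 1] over the
background) maximising the L1-penalized log-likelihood

    L(λ) = mean_pres λ·f(x) − log Σ_bg exp(λ·f(x)) − Σ_j β_j |λ_j|,

with β_j = β·s_j/√m, cloglog output 1 − exp(−e^H·raw), bootstrap 80/20
evaluation by rank-based AUC, 10 % training-omission thresholding and
threshold rescaling of the annual projections. Environmental axes are
principal components of annual bioclimatic variables (bio1–bio17 subset)
and of monthly insolation proxies. Realized niche volumes are delimited by
a one-class SVM in PCA space and integrated by Monte Carlo. Per-species
slopes are related to ecological traits (dispersal, euryocy, endangerment)
by general linear models with Type II partial η² effect sizes.

## Worked example

Run the full synthetic study (terrain → climate → records → SDMs → niches →
shift statistics → trait models) from one config:

```python
from alpshift.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(nx=40, ny=40, year_start=1961, year_end=1990,
                     n_species=12, records_per_year=8.0, replicates=5,
                     background_per_year=60, n_mc=4000, seed=3)
run_pipeline(cfg, "demo_out")
```

or equivalently `alpshift all --outdir demo_out --seed 3` from the shell.
`demo_out/summary.json` from this exact run reads (abridged):

```json
{
  "records": {"n_species": 12, "n_tmax_after_tmin": 10,
              "mean_z_alt": 3.30, "frac_z_alt_positive": 1.0},
  "sdm":     {"n_species": 12, "frac_z_alt_positive": 0.75},
  "auc_test_range": [0.860, 0.942],
  "niche_climate": {"min": 14.7, "max": 34.4, "median": 25.7}
}
```

Reading: under the configured warming of 0.03 °C/yr against a 0.0065 °C/m
lapse rate, an isotherm climbs ≈ 4.6 m/yr. The twelve virtual species are
programmed to track it at 0.4–1.0 of that rate depending on their dispersal
trait, so the record-based mean z_alt of 3.30 m/yr matches the programmed
mean (≈ 3.2 m/yr), every species trends uphill in its records, all SDMs
discriminate presences from background well (test AUC 0.86–0.94), and
specialist species occupy smaller climatic niche volumes than generalists.
Per-species slopes are in `demo_out/slopes.csv`, trait effect sizes in
`demo_out/trait_glm.csv`.

## Layout

- `alpshift.synthetic` — DEM, monthly climate, insolation proxy, virtual
  species and record sampling
- `alpshift.env` — bioclim variables, GWR/bilinear downscaling, PCA spaces,
  SWD tables, background sampling
- `alpshift.maxent` — the presence–background model, evaluation, projection
- `alpshift.niche` — one-class-SVM hypervolumes
- `alpshift.shifts` — altitudinal series and all trend statistics
- `alpshift.traits` — trait GLMs and OLS relations
- `alpshift.pipeline` / `alpshift.cli` — file-based stage orchestration
- `docs/methods.md` — model assumptions, parameter choices, limitations
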