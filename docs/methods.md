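# Methods

This note documents the models, the synthetic study system, the parameter
choices that matter, and what the verification experiments do and do not
demonstrate.

## The study system being emulated

The analysis targets the classic long-term mountain-records setting: a
single mountainous study region with a wide altitudinal gradient
(~400–3800 m), dated and georeferenced occurrence records of thermally
constrained species collected opportunistically over ~six decades, and
annual gridded monthly climate (minimum/mean/maximum temperature,
cumulative precipitation). Under a regional warming trend *w* (°C/yr) and a
temperature lapse rate *L* (°C/m), an isotherm — and with it the suitable
belt of a species whose distribution is temperature-limited — is expected
to move uphill at *w/L* metres per year. All parameter-recovery experiments
are built around this closed-form expectation.

## Synthetic data generator

**Terrain.** `make_dem` sums randomly oriented cosine ridges with a
smoothed Gaussian random field and rescales elevations to exactly
[base, base + amplitude] (defaults 400–3800 m). By default the elevations
are additionally rank-equalized (`hypsometry="uniform"`): the monotone
transform preserves ridge/valley topology but makes the hypsometric curve
uniform, so every elevation band offers equal area. This matters: with a
peaked area–elevation distribution the suitability-weighted median of a
shifting species drifts at measurably less than *w/L* (area availability
tugs the distribution toward the hypsometric bulk), i.e. the closed-form
recovery target would not be the truth of the simulation. `hypsometry="raw"`
keeps the unequalized field.

**Climate.** Monthly mean temperature is sea-level temperature + linear
warming trend − lapse·elevation + an annual seasonal cycle + a spatially
uniform N(0, noise_sd) anomaly per year-month (interannual fluctuations in
a small region are strongly coherent in space; a spatially uniform anomaly
also keeps the cell-to-cell temperature contrast exactly −L·Δelevation).
tmin/tmax bracket tmean at a fixed half-range (default 4 °C). Precipitation
is a constant monthly base with an optional linear orographic increase
(default +0.04 %/m) and multiplicative noise, floored at zero. Defaults:
lapse 0.0065 °C/m, warming 0.03 °C/yr (the recovery experiments use
0.04 °C/yr), seasonal amplitude 9 °C, noise 0.5 °C, 1200 mm/yr.

**Insolation.** A fixed-azimuth (180°, south) hillshade per month with a
monthly sun-elevation cycle, clipped at zero and scaled to a nominal
W/m²·h range. It is a slope/aspect proxy whose only role is to supply
topographic axes to the PCA, not a solar-geometry model.

**Species.** A virtual species is a product of independent Gaussian
suitability kernels on annual mean temperature and annual precipitation,
times a detectability in (0, 1]. Records per species-year are Poisson
(mean = records_per_year × detectability); record cells are drawn with
probability proportional to suitability, coordinates are exact cell centres
(the record-precision of real archives is unknown; cell centres make
elevation consistency exactly testable), and the date is a uniform day in a
June–August flight season (only the year is used downstream). A `tracking`
fraction in [0, 1] lets a species tolerate part of the warming in place:
its effective thermal optimum drifts with (1 − tracking) of the observed
regional anomaly, so its realized uphill velocity is tracking·*w/L*. The
pipeline's default species set programs tracking by dispersal class
(sedentary 0.4, intermediate 0.7, mobile 1.0) and thermal breadth by
euryocy (generalist 1.2 °C, specialist 0.6 °C), which gives the trait
models a known signal to recover.

What the generator does **not** emulate: spatial sampling bias and
observer-effort trends, detection that varies with year or weather,
population dynamics and local extinction debt, microhabitat and land-use
change, and spatially structured interannual climate anomalies. Passing
recovery tests therefore demonstrates estimator correctness under the
stated generating process, not robustness to these real-data pathologies.

## Environmental layers

Annual bioclimatic variables follow the standard bio1–bio19 definitions
with rolling three-month quarters (December–January wraparound, first
window on ties). The default retained set is bio1–bio7 and bio10–bio17;
the hybrid quarter variables bio8/bio9/bio18/bio19 are excluded as
artifact-prone. bio15 uses 100·sd/(mean + 1) to stay finite in arid cells.
Temperature seasonality (bio4) and precipitation seasonality use the
sample (n−1) standard deviation.

Geographically weighted regression downscaling fits, per fine cell, a
weighted least-squares regression of coarse temperature on coarse elevation
with a Gaussian distance kernel (default bandwidth 3 coarse cell sizes,
truncated at 4 bandwidths), evaluated at the fine elevation. Cells with
fewer than three positive-weight neighbours become nodata; a locally
constant elevation design falls back to the weighted mean. Precipitation
uses bilinear interpolation between cell centres with edge clamping. The
synthetic pipeline generates climate directly on the working grid, so
downscaling is exercised by its own tests rather than wired into the
default pipeline.

Both PCAs (bioclim; monthly insolation) z-score their inputs, drop
zero-variance columns with a warning, and retain components with
eigenvalue > 1 (sample n−1 convention, so eigenvalues sum to the retained
input count). The climate PCA is trained on year-matched extractions at the
records and projected onto every year's full grid; the insolation PCA is
static in time. SWD rows carry the scores of the record's own year.
Background points are uniform over finite cells, without replacement within
a year, resampled per year (default 1,000 per year; small demo configs use
less).

## Maximum-entropy model

Features are linear, quadratic and pairwise-product terms of the PCA axes,
min-max scaled to [0, 1] on the background (d axes → 2d + d(d−1)/2
features); out-of-range values at prediction time are clamped. The fit
maximises the penalized presence log-likelihood (README formula) by
accelerated proximal gradient ascent — FISTA with adaptive restart and a
backtracking line search, soft-thresholding for the L1 term — with
tolerance 1e−7 on the objective and a 5,000-iteration cap (a non-converged
fit is returned flagged). Per-feature penalties are β·s_j/√m with the
presence standard deviation floored at 1e−4 and β = 1 by default. Only the
objective of the reference Java implementation is replicated, not its
sequential update rule; agreement is verified against an independent
convex optimizer (split-variable L-BFGS-B) on small instances.

The raw output is the Gibbs density normalized over the training
background; entropy H is computed on that distribution and the cloglog
output is 1 − exp(−e^H·raw) (a uniform model yields 1 − e⁻¹ ≈ 0.632
everywhere). Evaluation repeats random 80/20 presence splits against the
full pooled background (the background is not resplit), reporting
per-replicate training/test AUC (rank-based, ties ½) and the mean 10 %
training-omission threshold — the sorted training score at 0-based index
⌊0.1·n⌋, so exactly the scores strictly below it are omitted. Annual
projections are thresholded, then rescaled as (p − t)/(p_max − t) — the
grammatically ambiguous rescaling rule is resolved so the surviving cells
span [0, 1] — and optionally masked by a binary land-cover grid.

## Niche volumes

A one-class SVM (RBF kernel) delimits each species' records in PCA space;
defaults nu = 0.05 and gamma = 1/(d·pooled variance), with a bounding box
one kernel bandwidth (1/√(2γ)) beyond the data per dimension. Volume is
box volume × the fraction of uniform box samples inside the boundary
(default 20,000 samples), with the binomial MC standard error. Absolute
volumes are implementation-relative: the boundary excludes ≈ nu of the
training mass while the kernel smooths it outward by O(bandwidth), two
opposing few-percent biases that do not vanish with more MC samples. Ratios
and ranks across species computed with the same settings are the meaningful
quantities, and only those should be compared across studies. Fewer than 5
records are refused; volumes are reported in PCA-space units with no
back-transformation.

## Shift statistics

Record-based z_alt regresses every individual (year, elevation) pair on the
year — not annual aggregates — so sparse years contribute proportionally.
SDM-based z_alt regresses the annual probability-weighted median elevation.
Weighted medians/quantiles use the smallest value whose cumulative
normalized weight reaches the target (equal weights reduce to the ordinary
lower-step quantile). Record-based annual range size is max − min; the SDM
analogue is the weighted p95 − p5 span, which is robust to single surviving
cells — a documented divergence between the two sources. VMR uses the
sample (n−1) variance; the weighted variant treats weights as frequencies
normalized to their sum with an n/(n−1) correction on the cell count.
Unweighted skewness is the adjusted Fisher–Pearson statistic
g₁·√(n(n−1))/(n−2); the weighted variant reports plain g₁ (SDM cell counts
are large, so the small-sample adjustment is immaterial). "Sites of
different altitude" means distinct elevations after rounding to 1 m;
annual skewness enters z_skew only for years with ≥ 5 such sites and
species with ≥ 5 qualifying years. Extreme-record ties are broken by the
earliest year. Decades are calendar decades; a species absent from a decade
is omitted from that decade's median anomaly.

## Trait models

Each response is modelled by OLS on the three categorical traits (treatment
contrasts; references sedentary / specialist / threatened) plus median
altitude as a continuous covariate, main effects only. Effect sizes are
partial η² = SS_effect/(SS_effect + SS_error) from Type II sums of squares
— the standard choice for unbalanced trait designs without interactions —
with the parametric F-test p per predictor and one r² per response model.
Constant (aliased) traits are dropped with a warning. Marginal means per
trait level are G-computation averages of model predictions with the trait
set to each level over the observed covariate distribution.

## Verification experiments and problem sizes

`alpshift.experiments` (used by `scripts/acceptance.py` and the test suite)
runs the study at sizes chosen to keep everything on a laptop-scale budget
while leaving the statistics well-determined: the velocity-recovery
experiment uses a 100×100 grid, 40 years, one well-sampled species
(30 records/yr), 200 background points per year and 10 bootstrap
replicates; the no-warming null uses 20 replicate 30×30, 20-year worlds.
In the recovery experiment temperature is deliberately the only
elevation-dependent climate driver (the orographic precipitation gradient
is switched off): with static elevation-correlated covariates present, a
correlative SDM legitimately attributes part of the apparent niche to them
and its surfaces then track the isotherm at slightly less than *w/L* —
covariate confounding that is a property of SDMs generally, not of this
implementation. The default pipeline keeps the orographic gradient.

## Known limitations

- No spatial autocorrelation correction, no detectability correction of
  records, no CRS handling (one planar synthetic coordinate system).
- Hinge/threshold/category Maxent features, clamping diagnostics and
  MESS-style extrapolation checks are not implemented.
- Absolute hypervolume values are estimator-relative (see above).
- The trait GLM assumes independent species (no phylogenetic correction).
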