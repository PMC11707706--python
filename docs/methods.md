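# Methods

`gardentrends` quantifies how individual rural gardens decouple from the
vegetation dynamics of their surrounding landscape, using long Landsat NDVI
time series. This note documents the model, its assumptions, the tunable
parameters, the synthetic-data generator, and the numerical conventions.

## The analysis

For every centroid (garden or abandoned-land-use reference) with NDVI
observations, the growing season May 1 - September 30 of each year is reduced
to two metrics:

* **greening**: the season mean of NDVI (dimensionless),
* **diversification**: the within-season sample variance of NDVI
  (dimensionless², divisor n-1 by default), a proxy for phenological and
  species variation.

Observations are restricted to centroids within 1 km (closed ball) of the
nearest village or hamlet center, and to two sensor-delimited eras:
E1 = Landsat 5, 1990-2011 and E2 = Landsat 8, 2013-2024. The gap year 2012 is
assignable to neither era; the eras are never mixed in one regression because
the two sensors differ radiometrically.

Per centroid, era and metric, the year series `v_t` is modeled by ordinary
least squares, `v_t = a + b * t + e_t`, with years centered at the era start
(slope unaffected; intercept conditioning improved). The trend of interest is
the slope `b` per year.

**Detrending.** Each garden is paired with its nearest reference centroid
(Euclidean, centroid-to-centroid, exact all-pairs scan, ties by smallest
reference id). The reference stands in for the quasi-natural background
(regional greening, phenology shift). Two subtraction modes:

* `fitted_line` (default): subtract the reference's fitted OLS line at the
  garden's years. Works when year sets differ between the pair.
* `paired_values`: subtract the reference's raw season metrics on common
  years.

**Significance.** A garden is decoupled in a metric when its detrended slope
is significant at strict `p < alpha` (default `alpha = 0.05`, two-sided t,
no multiple-testing correction; the summary reports the number of tests so
users can post-correct).

A statistical subtlety governs the p-value. Subtracting a *fitted line* is an
affine shift, which leaves the garden's own residuals unchanged: the naive
OLS p of the adjusted series therefore prices in only one fit's noise, while
the detrended slope `b_g - b_r` carries two. Under the null the naive t is
N(0, 2)-distributed and the rejection rate is `2 * Phi(-1.96 / sqrt(2)) ~
0.166`, three times nominal. The default (`reference_uncertainty =
"propagate"`) therefore tests the slope difference with the combined standard
error `sqrt(se_g^2 + se_r^2)` and Welch-Satterthwaite degrees of freedom,
which restores the nominal false-positive rate (verified by Monte Carlo; the
naive variant remains available as `"ignore"` and its ~0.17 null rate is
pinned by a test). In `paired_values` mode the reference noise enters the
residuals directly, so the plain OLS p is already calibrated and no
propagation is applied. Empirically the test runs slightly conservative
(~0.04) for the variance metric over the short 12-season E2 era, because
season variances of ~7 observations are noticeably skewed; pooled over both
eras the rate is within [0.04, 0.06].

**Classification.** Gardens with BOTH metrics significant are assigned the
sign quadrant of (greening slope, variance slope):

| label | greening | variance | reading |
|---|---|---|---|
| A intensification | + | - | homogenizing, managed greening |
| B naturalization | + | + | re-vegetation with rising variation |
| C artificialization | - | - | green-feature loss, sealing |
| D ruralization | - | + | variable private farming use |

Slope magnitude is carried to outputs but membership is sign-only. A garden
qualifies for the combined (map-ready) set when it is labeled in at least one
era; when both eras qualify, the representative label comes from the era with
the smaller `max(mean_p, var_p)` (ties to E1) — an invented but deterministic
rule; both per-era labels are always preserved.

**Summaries.** Per era: % of gardens with both trends significant, % with at
least one, and cluster shares over both-significant gardens. The primary
denominator is gardens with fittable series in the era; an alternative
including insufficient-data gardens is emitted alongside, since either
reading of "% of all garden centroids" is defensible. Rendered share tables
are rounded to 2 decimals with largest-remainder correction so they sum to
exactly 100.00.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | per-fit significance level, strict `<` |
| `village_radius` | 1000 m | closed-ball filter around village centers |
| `min_obs_per_season` | 3 | below this a season is dropped (variance needs >= 2; 3 adds stability) |
| `min_years_per_era` | 5 | below this a fit is an insufficient-data outcome (df >= 3) |
| `detrend_mode` | `fitted_line` | see above |
| `reference_uncertainty` | `propagate` | see above |
| `variance_divisor` | `n_minus_1` | `n` available for parity checks |
| `background_fallback` | `none` | `regional_mean` substitutes the era-mean reference trend when a paired reference is unfittable |
| `max_pair_distance` | none | optional cap on garden-reference distance |

## The synthetic generator

No deposited observation data ships with the package; the generator emulates
the stated world so every stage is testable. For garden g, year offset t,
day offset d after May 1:

    NDVI = mu0 + s(d) + (beta_bg + delta_g) * t + eps
    s(d) = A * cos(2*pi*(d - 76) / 365.25)          # peak ~July 16
    eps ~ N(0, sigma_g(t)^2)
    sigma_g(t)^2 = max(eps_floor * sigma0^2, sigma0^2 + (gamma_bg + gamma_g) * t)

so the expected within-season variance is `Var_d[s] + sigma^2(t)` — linear in
year with slope `gamma_bg + gamma_g` on top of a constant seasonal term.
References use `delta = gamma = 0`. Values are clipped to [-1, 1]; the
defaults keep clipping below 1% of observations so the linear model stays
honest. Observation counts are Poisson per season (mean 8, a realistic
cloud-thinned Landsat revisit yield over 5 months), thinned further by a 10%
missing rate; dates are uniform over the 153-day window; years <= 2012 are
tagged L5 and years >= 2013 L8, so 2012 is era-assignable to neither.

Defaults and why: `mu0 = 0.5` and `A = 0.15` (typical vegetated-land NDVI
with a moderate seasonal swing), `sigma0 = 0.05` (per-scene NDVI noise),
`beta_bg = 0.002 /yr` (a regional greening of ~0.07 NDVI over 35 yr),
`gamma_bg = 1e-5 /yr` (~10% background variance drift over the record),
`|delta| = 0.005 /yr` (a garden diverging by ~0.17 NDVI over 35 yr; large
enough to matter, small enough that clipping stays < 1%), `|gamma| = 5e-4
/yr` (~5x the detrended variance-slope SE over a 22-season era, the sizing
used in the recovery experiments), cluster mix 10% each of A-D and 60%
unlabeled. Coordinates are offset to Gauss-Krueger-like values so synthetic
tables always look like projected meters.

**A positivity constraint worth knowing.** A *negative* variance-trend
injection cannot stay linear indefinitely: `sigma^2(t)` hits the floor
`eps_floor * sigma0^2` once `|gamma| * t` approaches `sigma0^2`. With 8
observations per season, a gamma at 5x its estimator SE exhausts the starting
variance within a few seasons, so clusters A and C show a weakened (floored)
but never sign-flipped variance decline; they qualify as both-significant
less often than B and D, while qualifying gardens still carry the correct
label. Demonstrating a *sustained and detectable* negative variance trend
requires ~100 observations per season, which is what the dedicated property
test uses.

**What a green test does and does not establish.** The generator's noise is
Gaussian and i.i.d., its seasonal curve a single harmonic, its missingness
uniform; real Landsat NDVI has cloud-correlated gaps, sensor-specific
radiometry, autocorrelated weather-driven residuals and saturation at dense
canopy. Green recovery tests establish that the pipeline's estimators and
gates recover the structure they target under the stated model — not that
the published landscape-scale percentages are reproduced; those depend on
the deposited Brandenburg data, which is imported via the (deliberately
unimplemented) `import_deposit` adapter.

## Numerical conventions and edge cases

* Exact fits (residual sum of squares exactly 0) take `p = 0`; a
  "significant" slope of exactly 0 (degenerate input) classifies as `none`
  with a logged warning.
* Nearest-reference ties are broken by lexicographic reference id; the
  all-pairs scan is exact, chunked for memory.
* Years are centered at the era start before fitting; detrending is invariant
  (to 1e-9) under adding any affine function of year jointly to garden and
  reference observations.
* Gardens whose paired reference is unfittable in an era are
  insufficient-data outcomes by default (no silent fallback); the
  `regional_mean` fallback is opt-in.
* Runs are pure functions of (config, inputs): the manifest carries no
  timestamps, so reruns are byte-identical across CSV/JSON/GeoJSON outputs.
* The village-radius boundary is closed (`<=`), the conventional reading of
  "radius = 1 km".

## Known limitations

* No autocorrelation-robust inference, no Theil-Sen option, no breakpoint
  detection; trends are single straight lines per era.
* No multiple-testing correction by design (per-fit gating); interpret
  landscape percentages accordingly.
* The deposit importer is a stub; shapefile and raster I/O, CRS reprojection
  and cloud masking are out of scope (inputs are assumed cleaned NDVI at
  projected planar coordinates).
* The combined-set representative-label rule is a package convention, not an
  estimate of anything; per-era labels are authoritative.
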