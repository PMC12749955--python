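# Methods

## The Soil Degradation Proxy

The SDP condenses four topsoil indicators — water-erosion rate, electrical
conductivity (EC, a salinity proxy), pH, and soil organic carbon (SOC) —
into one continuous degradation score per sample. Each indicator is first
mapped to a soil health indicator (SHI) in [0, 1] by its empirical CDF with
a direction rule; the SDP is the weighted mean of the four SHIs with equal
weights (0.25) by default. The construction is purely rank-based, so SHIs
are invariant under strictly monotone transforms of the raw scale, and the
score is *relative to the reference survey*: an SDP of 0.85 means "worse
than most sampled sites", not an absolute physical quantity.

### ECDF convention

The base ECDF is F(x) = (rank − 1)/(n − 1) on the fitted reference sample.
This convention (rather than rank/n) is forced by the endpoint rule that
the sample minimum maps to 0 and the maximum to 1. Interior ties share the
mean rank; values tied with the minimum or maximum are pinned to 0 or 1 so
the endpoint rule survives duplicated extremes. Unseen interior values are
linearly interpolated between the neighboring reference values (a step
evaluation differs only below the data resolution and would make the SHI
discontinuous); queries outside the reference range clamp to {0, 1} so
prediction-time inputs can never leave [0, 1].

### Direction rules

Erosion and EC use *more is worse* (SHI = F); SOC uses *less is worse*
(SHI = 1 − F). pH uses an *inverse optimum* around a pivot of 6.5, the
midpoint of the broadly favorable 4.9–8.1 range: SHI = F above the pivot
and 1 − F below it, so degradation grows as pH departs toward either acid
or alkaline extremes. Exactly at the pivot we define
SHI = min(F(6.5), 1 − F(6.5)), the continuous-minimal completion of the
two one-sided branches; any other choice would put a spike or gap at the
curve's minimum. Rescalers are fitted once on the pooled survey (all
survey years together): per-year ECDFs would rescale each year against a
different reference and make SDP values incomparable across years.

## Bootstrap random-forest ensemble

The survey is split once into 70% training / 30% validation by a seeded
uniform permutation (unstratified). The ensemble holds `n_models`
independent random-forest regressors (default 100), each fitted to a
with-replacement resample of the *training split only*; the validation
rows never enter any member's fit, so validation metrics are honest for
the whole ensemble. Defaults: 500 trees per member, features-per-split
p/3 rounded, variance split criterion — all exposed in `EnsembleConfig`.
Categorical predictors (land cover, lithology) are integer-coded against
a level registry persisted with the ensemble; forests split ordinally on
these codes, which is adequate at this cardinality, and one-hot encoding
is available via config. Unseen levels at prediction time map to an
"other" level when the training data had one, else to the first
registered level, with a warning.

The ensemble mean is the point prediction (used for maps and
interpretation); predictions are clipped to [0, 1] because the SDP is
bounded by construction. Ensemble uncertainty is the difference between
the 95th and 5th percentiles of the member predictions per pixel, with
percentiles computed by linear interpolation between closest ranks
(numpy's default convention).

Accuracy is reported as R² = 1 − SSE/SST, RMSE and MAE per member on both
splits, plus an error summary over ten equal SDP intervals on [0, 1] —
sparsely sampled intervals (typically the low-SDP tail) show visibly
larger errors, which is an honest property of data-scarce regions rather
than a defect of the metric.

## Interpretation

*Gini importance* is the mean decrease in node impurity per predictor,
averaged over members and normalized to sum to 1 (one-hot groups, if used,
are summed back into their parent predictor).

*One-SD sensitivity* perturbs a single continuous predictor by one
training-set standard deviation for every evaluation row, holding all
else fixed, and reports the mean change in predicted SDP; the sign carries
the direction of the response, and the statistic can be computed per
land-cover stratum. For a linear model f = βx this equals βσ exactly,
which the tests exploit as an analytic oracle.

*First-order ALE* uses quantile bin edges over the chosen stratum
(default 20 bins). Bin k spans (z_{k−1}, z_k], with rows at the first
edge joining bin 1; the local effect of bin k is the mean of
f(x_j = z_k) − f(x_j = z_{k−1}) over its rows, accumulated by cumulative
sum. Empty interior bins (possible after deduplicating quantile edges)
contribute a zero step, equivalent to merging with the left neighbor, and
are logged. The accumulated curve is centered so that its piecewise-linear
evaluation at the stratum's data points has mean zero; with this
convention the centered ALE of a linear additive model is exactly
β(z − x̄), and the curve reads as the departure from the stratum's average
prediction, which is reported alongside as an additive offset. ALE is
evaluated against the ensemble-mean predictor. The 95% band comes from 50
row-bootstrap resamples (default) re-evaluated on the edge grid fixed
from the full sample; resampling rows without refitting measures the
estimation uncertainty of the curve given the model. Refitting the
ensemble per resample — which also propagates model-fit variance — is
available via `refit=True` at roughly `n_boot ×` training cost.

Exploratory statistics use Pearson correlation of SDP with each predictor
within land-cover strata (rank correlation is a config option) and
per-class SDP count/median/quartiles.

## Annual maps and trends

For each year the ensemble predicts every valid pixel from that year's
covariates (static layers reused; erosion is an ingredient of the training
response, never a predictor). Nodata propagates: a pixel missing any
predictor is missing in every product. Prediction may be tiled to bound
memory; tiling cannot change results because members predict row-wise.

Trends regress each pixel's SDP series on calendar year (so slopes are in
SDP units per year) by closed-form OLS with an intercept; two-sided
p-values come from the slope t statistic with n − 2 degrees of freedom.
Pixels with p ≥ α (default 0.01) or |slope| ≤ 0.001 are masked as
not-significant-or-negligible; moderate trends occupy (0.001, 0.003] and
strong trends exceed 0.003, signed by the slope. The boundary values fall
on the documented sides: exactly 0.001 is negligible, exactly 0.003 is
moderate. A perfectly linear series has zero residual variance and is
reported with p = 0 and a degeneracy flag. Missing years are allowed when
at least three (year, value) pairs remain. No multiple-testing correction
is applied across pixels by default, mirroring the per-pixel decision
rule; Benjamini–Hochberg FDR is available behind a flag. Area summaries
report, per land-cover class, the fraction of valid pixels in each trend
category (fractions sum to 1 within a class).

## Synthetic data generator

The generator emulates the two inputs the pipeline needs: a two-year
point survey (default 2 × 2,500 points, survey years 2015 and 2018) and
annual covariate grids for 2000–2022 on a shared 64 × 64 north-up grid
(defaults; all configurable). Covariates are seeded Gaussian white noise
convolved with a Gaussian kernel (σ = 6 pixels), standardized, and
combined with latitudinal gradients for the climate fields (the south is
warmer by 8 °C across the grid by default and drier); soil texture
fractions are a softmax of three smooth fields with silt closing the
simplex exactly; land cover (cropland 40%, forest 30%, grassland 20%,
other 10%) and five lithology classes come from thresholding further
smooth fields, which yields contiguous patches so stratified analyses
have non-trivial geometry. Dynamic layers (5-year precipitation and
temperature, NDVI, NDTI) vary around their 30-year baselines with small
seeded yearly anomalies plus a gentle warming/greening drift, giving the
trend stage something real to find. About 2% of pixels form a contiguous
nodata blob to exercise mask propagation.

Indicators follow a documented generative link: a latent degradation
field L is the sum of effect sizes times standardized covariates
(temperature and clay increase L, precipitation and NDVI decrease it,
by default) plus a land-cover offset (cropland +0.3, forest −0.3) and
Gaussian noise of scale `noise_sd` (default 0.1). Erosion and EC are
lognormal increasing functions of L, SOC a lognormal decreasing one, and
pH departs from 6.5 by a logistic ramp in L with a random side — so the
inverse-optimum rule is genuinely exercised. Erosion is generated once
per pixel from the reference survey year and held constant across survey
years, matching the treatment of modelled erosion as static between
campaigns. The per-row latent L is stored in the table, making parameter
recovery a first-class test: with 5,000 survey rows and `noise_sd` 0.05
a 10-member ensemble reaches held-out R² of at least 0.8, and R² falls
monotonically as `noise_sd` grows (checked at 0.05 / 0.2 / 0.8).

What the generator does **not** emulate: real European geography and the
LUCAS sampling design, spatially correlated *indicator* noise, covariate
measurement error, heterogeneous native resolutions (all synthetic layers
are born on one grid), and class-dependent indicator variance. Passing
tests therefore demonstrate that the pipeline recovers a known link under
realistic smoothness and noise — not that any particular real-data
accuracy will be achieved.

## Numerical and design choices

- Rasters are written as one TIFF per layer-year plus a JSON sidecar
  carrying the geotransform, nodata convention and categorical legends;
  float nodata is NaN, integer nodata −9999. Round trips are bit-exact.
- Grid geometry: row 0 is the northernmost row, pixel-center
  registration, half-open pixel intervals; survey points snap to their
  containing pixel.
- All randomness flows from integer seeds through
  `numpy.random.default_rng([seed, stage, ...])` streams; the pipeline's
  single global seed is propagated to the generator and the ensemble, and
  two runs with one config produce identical checksums for every output
  file (the demo pipeline run in the acceptance tests verifies this).
- Rescalers serialize to JSON with the sorted reference sample embedded;
  Python float repr guarantees bit-exact round trips.
- Problem sizes in the test suite (16–64 pixel grids, hundreds to
  thousands of survey rows, 3–10 member ensembles with 15–500 trees) were
  chosen as the smallest sizes at which each property is stable across
  seeds; the full-size defaults (100 members × 500 trees) remain the
  package defaults.

## Known limitations

- The SDP is reference-relative; comparing SDP values across studies
  requires a shared reference sample (here: the pooled survey years).
- Equal SHI weights are a normative choice; landscape- or
  ecosystem-dependent weighting and alternative pH optima are not
  implemented.
- The 70/30 split is unstratified; spatially blocked validation would be
  stricter under spatial autocorrelation and is left to the user.
- The trend stage assumes the annual maps are comparable over time, which
  holds here because one pooled-reference model predicts all years.
- Nearest-neighbor resampling is provided only as a convenience for user
  rasters; no reprojection between coordinate systems is attempted.
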