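# Methods

## Model and assumptions

`vprmsif` treats the land surface as a mosaic of eight vegetation classes
(Grassland, Cropland, Savanna, Shrubland, Deciduous/Evergreen/Mixed
forest, and `Other` for water and unclassified cells) on a regular
geographic grid of center-registered cells: a cell with center c and
resolution r spans [c − r/2, c + r/2). This registration makes
0.05° → 0.1° nesting exact, which the block-mean regridding of the fine
SIF product relies on. Time is discretised into the 8-day composite
calendar that satellite reflectance products use: periods restart at
day-of-year 1 each year, giving 46 periods with the last truncated to 5
(or 6) days. Missing data travel as numpy masks end to end; no sentinel
values.

### Standard light-use-efficiency fluxes

GPP per cell, composite and class is

GPP = |λ| · Pscale · Tscale · Wscale · EVI · SWdown / (1 + SWdown/SWdown0)

- **EVI, LSWI.** Computed with the standard MODIS-style formulations:
  EVI = 2.5(NIR−Red)/(NIR + 6·Red − 7.5·Blue + 1), masked where the
  denominator is non-positive; LSWI = (NIR−SWIR)/(NIR+SWIR). The absorbed
  photosynthetically active radiation fraction is taken equal to EVI with
  no offset variant applied.
- **Tscale** follows the Raich terrestrial-ecosystem form,
  (T−Tmin)(T−Tmax) / [(T−Tmin)(T−Tmax) − (T−Topt)²], zero at and outside
  [Tmin, Tmax]; ties at exactly Tmin/Tmax resolve to zero (photosynthesis
  absent). Defaults Tmin/Topt/Tmax = 0/20/45 °C for every class.
- **Pscale** = (1+LSWI)/2, pinned to 1 for evergreen forest (no leaf-age
  effect) and at maximum greenness, and 0 over `Other`. "Maximum
  greenness" is operationalised per cell as any composite whose EVI is at
  least 99 % of that cell's annual maximum; the fraction is configurable.
- **Wscale** = (1+LSWI)/(1+LSWImax) with LSWImax the per-cell maximum over
  the full calendar year (no growing-season subsetting; the annual maximum
  is the growing-season maximum for any season definition containing the
  peak). LSWImax = −1 yields a masked result.
- **λ sign.** The packaged European parameter set prints λ with the
  uptake-negative sign convention; GPP is computed with |λ| and always
  reported as a positive uptake magnitude.

Baseline respiration is R_eco = α·max(Tair, Ttshld) + β per class, with
Ttshld defaulting to 0 °C (configurable); the clamp keeps winter
respiration from going negative. `Other` cells carry zero flux.

Packaged per-class (λ, SWdown0, α, β) tables are provided for a
tropical-biome calibration and a European-biome calibration. Units:
λ in µmol CO2 m⁻² s⁻¹ per µmol SWdown m⁻² s⁻¹, SWdown0 in the same units
as SWdown, α per °C, β in µmol CO2 m⁻² s⁻¹.

### SIF harmonization

The two SIF products differ by a roughly constant per-biome multiplicative
offset (different retrieval wavelengths, 743–748 vs 757 nm, and an
upscaling step). After block-averaging the fine product to the coarse
grid, the per-class factor S is estimated as the **ratio of sums** of
matched 8-day pairs: robust, reproducing a mean multiplicative offset, and
making the per-class sums of the scaled product equal the target exactly.
A least-squares slope through the origin is available behind
`estimator="slope0"`. R² is the squared Pearson correlation of the
matched pairs. Classes with fewer than `min_pairs` pairs (default 2) or a
zero-sum denominator are omitted with a warning.

### SIF → GPP and the coefficient transfer

GPP = γ(vg)·SIF + C(vg), floored at zero (retrieval noise can drive the
line negative; GPP is a magnitude). GOSIF-side (γ, C) are packaged
constants; TROPOSIF-side values follow by dividing both by S(vg), and the
packaged TROPOSIF-side table reproduces that division to two decimals
(round-half-even) for all seven classes.

**Known inconsistency.** Dividing *both* coefficients by S makes the two
conversion routes disagree by C·(1 − 1/S) per class even when the products
differ by exactly the factor S: substituting TROPOSIF = S·GOSIF into the
TROPOSIF-side line gives γ·GOSIF + C/S, not γ·GOSIF + C. Only the slope
terms cancel. The transfer rule and the printed coefficient table are
internally consistent with each other and are implemented as given; the
acceptance suite contains one deliberately failing test asserting the full
composition identity, and the acceptance script reports the measured
discrepancy (≈1.9 µmol m⁻² s⁻¹ at the evergreen-forest intercept)
rather than hiding it.

### GPP refinement

GPP_refined = η(vg)·GPP_model + ε(vg), floored at zero. The default η is
implemented literally as Σ(GPP_SIF·GPP_model)/Σ GPP_model over all cells
and composites of the class. Note this estimator is a GPP-weighted mean
of the SIF-based GPP and carries GPP units; it typically yields large η
and strongly negative ε, and the non-negativity floor then lifts the
refined class mean above the SIF-based one. The dimensionally
conventional slope-through-origin estimator Σ(GPP_SIF·GPP_model)/
Σ GPP_model² is provided behind `estimator="slope0"` and produces η of
order 1–3 on the synthetic scenes. In both cases ε is defined as the mean
residual after η, which makes the (unclipped) refined field mean-unbiased
per class on the fitting sample — the property the tests verify. The
slope-through-origin variant recovers an exact proportionality
GPP_SIF = a·GPP_model to machine precision; an affine relation with a
non-zero offset is *not* exactly recoverable by a through-origin slope,
so the recovery test is stated at zero offset.

### Respiration refinement

Three experiments extend the baseline term B = α·max(Tair,Ttshld)+β:

- SM: R = ν·SM + κ·B
- ST: R = τ·ST + κ·B
- SMST: R = τ·ST + ν·SM + κ·B

"Adjusted against" reference fluxes is operationalised as per-class
ordinary least squares with **no free intercept** — κ multiplies the whole
baseline and thereby absorbs its intercept β. The fit is a plain
least-squares solve on at most three columns with an explicit rank check;
rank-deficient designs are omitted with a warning naming the collinear
predictors. Units are checked conventions, not conversions: SM as
volumetric fraction (m³ m⁻³), ST in kelvin, Tair in °C. Predictions are
floored at zero. Least-squares nesting guarantees fitted RMSE ordering
SMST ≤ SM ≤ baseline and SMST ≤ ST on the fitting sample, which is the
testable counterpart of the improvement a real eddy-covariance comparison
would show. Reference fluxes of either provenance (FLUXNET-like or
FLUXCOM-like) enter as an ordinary gridded field.

### Evaluation

R² is the squared Pearson correlation (undefined — NaN — for zero-variance
series), RMSE the root-mean-square error, MBE the mean of model minus
reference (under-prediction is negative). These satisfy
RMSE² = MBE² + var(model−reference), which is tested. Monthly means of
8-day composites apportion straddling composites to both months in
proportion to overlap days.

## Synthetic scenes

The generator fabricates every input on a default 16 × 21-cell 0.1° domain
(0.05° for the fine SIF product) over one composite year, deterministic
given its seed:

- a block class layout covering all seven biomes plus a few `Other`
  cells (uniform and checkerboard layouts available);
- reflectance bands inverted from class-specific sinusoidal EVI/LSWI
  seasonal cycles (monsoon-peaked for herbaceous and deciduous classes,
  flat-high for evergreen forest) with ~5 % fixed spatial texture, so the
  derived indices follow the configured seasonality and stay in range;
- seasonal air temperature (12–34 °C), shortwave radiation
  (80–850 µmol m⁻² s⁻¹), soil moisture (0.08–0.42 m³ m⁻³) and soil
  temperature (291–309 K);
- a fine-grid SIF product with per-class seasonal cycles, and a coarse
  product equal to s₀(vg) times its block mean plus Gaussian noise
  (σ = 0.1 mW m⁻² sr⁻¹ nm⁻¹ by default); the s₀ defaults are the packaged
  per-class reference factors (2.81–4.62);
- a reference respiration field built from known per-class (τ₀, ν₀, κ₀)
  plus Gaussian noise (σ = 0.1 µmol CO2 m⁻² s⁻¹ by default). The truth
  coefficients are sized so each term contributes order-1 fluxes and the
  totals fall in the 1–10 µmol CO2 m⁻² s⁻¹ range typical of site-level
  respiration;
- a designated deciduous-forest cell serving as a pseudo
  eddy-covariance site for monthly site-level evaluation.

At the default sizes each vegetated class contributes ≈2 000
composite-cell samples, which puts the noisy-recovery checks in the
regime where fitted coefficients fall within three standard errors of
truth.

What the scenes do *not* emulate: radiative-transfer physics, cloud-gap
structure beyond masking, cross-correlated retrieval errors between the
two SIF products, drought decoupling of the SIF–GPP relationship, or real
amplitude calibration. Passing recovery tests therefore demonstrates the
correctness of the estimators under the model's own assumptions, not the
fidelity of those assumptions to any real landscape.

## Numerical choices

- Regridding requires exact nesting (integer resolution ratio, aligned
  edges) and errors otherwise; the estimator is the block mean over
  non-missing fine cells, so partially observed blocks average their
  observed cells only and the domain mean is conserved on fully observed
  data. The regridding estimator is a package choice; nearest-neighbour
  assignment is not offered.
- Per-class fits drop pairs with either side missing; classes are omitted
  (with warnings) rather than extrapolated when data are insufficient.
- Comparisons to the packaged two-decimal coefficient tables use
  round-half-even.
- Grid equality uses a relative tolerance of 1e-6 on spacing and centers.
- Floors at zero apply to output *fluxes* (GPP, refined GPP, predicted
  respiration); fitting always uses the unfloored linear predictors.

## Problem sizes

The test suite and the acceptance script run on the default 16 × 21 × 46
scenes (≈15 000 vegetated samples; ≈2 200 per class) and complete in a few
seconds; these sizes were chosen as the smallest giving well-conditioned
per-class fits with all eight classes represented.

## Known limitations

- Hourly meteorology and NEE assembly with atmospheric transport are out
  of scope; inputs are 8-day composites throughout.
- Vegetation maps are static; no season- or year-dependent class change.
- The literal η estimator's dimensional quirk (above) is preserved by
  design; users wanting a conventional regression slope should pass
  `estimator="slope0"`.
- GeoTIFF vegetation maps are not supported; maps travel as NetCDF integer
  codes with an embedded JSON legend.
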