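# Methods

This note documents the models, numerical choices and limitations behind
`forestcarbon`.  The package estimates forestation-induced changes in
ecosystem carbon stocks from a paired control/forested plot design and
upscales them to regional totals.

## The paired design

Every quantity of interest is a *pair delta*: the forested-plot value minus
the value of the non-forested control plot at the same site (same soil type
and prior land use, typically within 50–100 m).  The design estimates the
effect of forestation without before/after data; its key assumption is that
the control represents what the forested plot would look like unplanted.
Deltas can be negative (biomass or SOC loss relative to background) and the
pipeline preserves their sign everywhere.  ΔTOCD is defined as the exact
sum Δ(biomass density) + ΔSOCD and is computed as such, never re-measured.

## Biomass carbon (allometry module)

Per-tree timber volume uses the two-predictor power law
`V_i = a·DBH^e·TH^f` with DBH in cm, TH in m and V in m³.  Plot volume is
the plain sum over measured stems (all trees taller than the 2.5 m survey
threshold; a permissive flag admits other data).  Stand biomass follows the
biomass-expansion-factor method, `B = cf·(b·V + c)/A`:

* `A` — plot area, default 400 m² (20 × 20 m survey plots);
* `b, c` — species-specific expansion constants (kg dry mass per m³ of
  timber volume, and the volume-free intercept);
* `cf` — carbon fraction of dry biomass, default 0.5 and configurable per
  species.  Published expansion constants are sometimes calibrated directly
  to carbon; in that reading `cf` should be set to 1.  The schema carries
  `cf` explicitly so either convention can be expressed; the package never
  silently assumes one.

The shipped coefficient table is a **placeholder** with plausible
magnitudes; real analyses must supply calibrated, unit-consistent
`coefficients.csv`.  Control-plot biomass comes from a cell-registered
gridded background-biomass map (nearest-cell lookup, half-open cell
extents, edge ties to the lower-left cell); a point outside the map or on a
masked cell excludes the pair with a logged reason.

## Soil carbon and nitrogen (soil_carbon module)

Each plot is sampled by three replicate profiles over six fixed layers
(0–5, 5–10, 10–20, 20–30, 30–60, 60–100 cm; thicknesses 5, 5, 10, 10, 30,
40 cm).  Organic carbon content is `SOCC = STCC − SICC`; negative raw
differences (measurement noise) are clamped to zero and flagged rather than
dropped.  Layer density is

    D_j = content_j · (SDW_j / V) · w_j · U

with content as a mass fraction, `SDW/V` the dry fine-soil mass over total
ring volume (this product realizes bulk density × soil volume fraction,
g cm⁻³) and `w_j` in cm.  Dimensional analysis fixes the unit conversion at
`U = 10` for kg m⁻² output (1 g cm⁻² = 10 kg m⁻²); a conversion of 10² as
sometimes printed for this formula would inflate densities tenfold, so the
package derives `U` from the declared units instead of copying a constant.
Input content units are declared per row (`fraction | percent | g_per_kg`)
and normalized on read.

Replicate layer densities are averaged, then summed over the layers
present.  Cores that could not reach 1 m simply sum fewer layers and carry
`complete_to_1m = False`; no imputation is attempted.  Pair deltas are
computed over the *common* layer set of the two plots and flagged when the
depths differ, so a truncated member cannot bias the comparison.

## Inference (paired_stats module)

**Group tests.**  Two-sided one-sample t tests of each group's deltas
against zero, with Benjamini–Hochberg FDR adjustment across the groups
tested in one call (the FDR family is one call; the package does not pool
families across analyses).  Stars follow the 0.05/0.01/0.001 thresholds on
the adjusted p.  Groups with n < 2 or zero variance are marked untestable
and excluded from the family.

**Mixed model.**  Gradient slopes (delta vs stand age, delta vs STND) use
`y = β₀ + β₁x + u_site + ε`, `u ~ N(0, σ_u²)`, `ε ~ N(0, σ_e²)`, fitted by
restricted maximum likelihood.  The implementation profiles the variance
ratio λ = σ_u²/σ_e²: for fixed λ the per-site covariance `I + λJ` inverts
analytically (Sherman–Morrison), giving closed-form GLS fixed effects, and
a bounded one-dimensional minimizer works on log λ ∈ [log 1e−8, log 1e6].
The boundary λ → 0 is checked explicitly; there the fit *equals* ordinary
least squares and is flagged `reduced_to_ols`, not treated as a failure.
Confidence intervals use a t reference with containment degrees of freedom
`n_obs − n_groups − 1`, a deliberate, documented approximation (simulation
in the test suite shows ~95–97% coverage at the default conditions).

**Species trade-off.**  Per species (≥3 pairs), the slope of Δ(biomass) on
stand age and of ΔSOCD on background STND, both from the mixed model;
species represented by a single site fall back to OLS and are flagged.

## Upscaling (upscaling module)

The model tree ensemble consists of regression trees whose internal nodes
split by maximum variance reduction and whose leaves hold least-squares
linear models over the continuous predictors (MAP, MAT, stand age, lon,
lat); species enters splits through one-hot indicators.  Randomization is
bootstrap row resampling plus per-node feature subsampling
(`feature_fraction` 0.7).  Defaults: `min_leaf` 10, `max_depth` 8,
candidate pool 100, retain the best 20 by validation MSE on the common
20% hold-out (an out-of-bag scoring mode is available behind
`selection="oob"`); the ensemble prediction is the member median.  Leaf
predictions are clipped to the training response range — a standard
safeguard against linear-leaf extrapolation on grid cells outside the
fitted hull.  Degenerate inputs (constant response, too few rows) yield a
single-leaf tree returning the mean; rank-deficient leaf regressions fall
back to the leaf mean.

Totals weight the mean predicted density change per province × species by
planted area, `Σᵢⱼ Xᵢⱼ Aᵢⱼ`, with the dimensional conversion
kg C m⁻² · km² = 10⁻³ Tg C.  The 'other' species group's density is set to
the per-province mean of the five major species.  Average densities are
totals divided by total planted area, so the internal identity
average × area = total holds by construction.  Uncertainties repeat the
full split→train→predict→aggregate chain with independent seeds and report
sd/√n_repeats of each total (a convention, stated here because "standard
error over simulations" admits several).

## Gradient analyses (gradient_analysis module)

Binned surfaces use half-open `[lo, hi)` bins on both axes (a point on an
interior edge joins the upper bin; points at or beyond the last edge are
counted as outside and reported, so bin counts conserve the in-range
total).  Default 20 intervals per axis over the data range.  Marginal
profiles are n-weighted means over the collapsed axis.  The ΔSOCD/Δ(biomass)
ratio is defined only where |Δbiomass| ≥ ε (default ε = 0.05 kg C m⁻²).
Sign classes use strict signs; exactly-zero or missing deltas are
'undefined' and excluded from the fractions, which makes the invariant
exact that every 'contrasting' (mixed-sign) cell has a negative ratio
wherever the ratio is defined.  Class fractions are computed over
planted-mask cells only.

## Synthetic survey (synthetic_data module)

The generator reproduces the survey *design*: 163 sites (configurable),
each with one control and a shifted-geometric number of forested plots
capped at 26 (success probability 0.266, expectation ≈3.8 plots/site,
i.e. ≈614 forested plots — the scale of the emulated campaign), five
dominant species plus 'other' drawn by weight, integer stand ages 5–50 yr,
MAT −8…16 °C and MAP 300…1300 mm on smooth lat/lon gradients plus noise,
and background STND lognormal around 0.9 kg N m⁻² with a spatial trend
toward the cooler/wetter north-east (mimicking the nitrogen-rich phaeozem
belt; the trend is what makes geographic upscaling informative).

Ground-truth responses are phenomenological, not process-based:

* Δbiomass(age, STND, species) = rate_sp · age · exp(−(STND−opt)²/2w²) —
  linear in age (rates 0.06–0.30 kg C m⁻² yr⁻¹ across species, fastest for
  larch and Mongolian pine, slowest for Chinese pine), unimodal in nitrogen
  (optimum 1.2 kg N m⁻², width 0.8; width `None` disables the hump);
* ΔSOC(STND, age, species) = slope_sp · (STND − 1.4) · min(age/20, 1) —
  monotone decreasing in nitrogen with species slopes −0.8…−3.5
  kg C m⁻² per kg N m⁻², steepest for the fastest growers (the configured
  carbon–nitrogen trade-off), positive below the 1.4 kg N m⁻² zero
  crossing and negative above it, saturating by stand age 20.

Tree lists invert the allometric chain: the target plot biomass fixes the
target volume; DBH is lognormal with age-increasing median (median
5 + 0.4·age cm, σ = 0.3), height follows 1.3 + 0.6·DBH⁰·⁸ m plus noise
(floored above the 2.5 m survey threshold), and DBH is rescaled by
`(V_target/V_raw)^(1/e)` so the summed volume matches exactly.  Soil
profiles spread the target plot densities over the six layers with fixed
fractions (0.25, 0.18, 0.18, 0.14, 0.15, 0.10) and depth-increasing bulk
densities 1.1–1.5 g cm⁻³, so integration recovers the targets; cores are
truncated at 30 cm with probability 0.02 to exercise the missing-layer
policy.  Controls carry a biomass value looked up from a generated
background raster rather than a tree list, matching how controls are
treated in the analysis.  Noise defaults (0.8 kg C m⁻² on the biomass
response, 0.4 on the soil response, 5% relative on replicate contents)
produce pair-delta scatter comparable to field data; with all noise off the
pipeline recovers the configured surfaces to numerical precision, which the
test suite exploits.

What the generator does **not** emulate: litter/decomposition dynamics,
spatially autocorrelated residuals beyond the smooth trends, measurement
censoring, species–site selection effects, or realistic province
geometries (provinces are nominal longitude bands).  Passing tests
therefore demonstrate correctness of the accounting and inference
machinery under the stated statistical structure, not the field validity
of any ecological conclusion.

## Problem sizes and determinism

The default acceptance run uses the full 163-site survey, a 48 × 72
predictor grid (≈2,400 planted cells), a 60-candidate ensemble and 5
uncertainty repeats; the test suite uses 40-site surveys and 20–40
candidate pools.  These sizes keep a complete run in seconds while leaving
every estimate comfortably stable.  All randomness flows from explicit
seeds through `numpy.random.default_rng`; a fixed seed reproduces every
table byte-for-byte, and each CLI stage records its seed and input
checksums in a JSON manifest.

## Known limitations

* The placeholder allometry constants are not species-calibrated; absolute
  synthetic biomass levels are only order-of-magnitude realistic.
* The mixed model fits a single predictor with a random intercept only (no
  random slopes, no multi-predictor fits), matching its intended use.
* Containment df for mixed-model CIs is an approximation; exact
  Satterthwaite/Kenward–Roger corrections are out of scope.
* Soil-change fields for upscaling are accepted as inputs (or synthesized);
  the package does not implement an independent SOC upscaling model.
* Grids are plain lon/lat tables; no projection handling or map rendering
  beyond simple helpers.
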