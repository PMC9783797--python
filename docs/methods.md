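# Methods

## The model

The composite index treats regional ecological quality as a per-pixel,
per-date latent variable expressed by four observable indicators —
greenness (NDVI), dryness (NDBSI), wetness (tasseled-cap moisture) and heat
(land surface temperature) — and summarizes a year (or season, or month) as
the per-pixel mean of single-date index values. Three methodological
choices distinguish it from the classic single-scene RSEI:

1. **Full-sequence normalization.** The min-max transform
   x\* = c + d·(x − min)/(max − min) is fitted with extrema taken jointly
   over every valid pixel of every date. Being a single strictly
   increasing affine map per indicator, it preserves the order of *any*
   two observations across dates; a per-scene ("static") map preserves
   order only within one date and demonstrably inverts it across dates.
   Defaults c = 0, d = 1 put every indicator on [0, 1].
2. **Sign-stabilized PC1 aggregation.** The single-phase index is the
   projection of the normalized indicator vector onto the first
   eigenvector of the indicator covariance matrix. Eigenvectors are
   defined only up to sign; the convention here is that the NDVI loading
   is positive (greenness improves quality), and the whole vector is
   negated when a solver returns the opposite orientation. An exactly
   zero NDVI loading is refused rather than guessed. The projection is
   computed as the raw dot product v·x, which equals the centered
   projection plus the projected mean and therefore induces the same
   ordering.
3. **Multi-temporal mean.** Per pixel, the period index is the arithmetic
   mean over the dates where the pixel is valid, with an explicit
   observation-count raster. Duplicate observations of one calendar date
   are averaged into a single phase first so scene overlap cannot
   double-weight a pixel. Phases are unweighted. Before averaging, the
   per-date projections are rescaled once by a min-max over *all* phases
   jointly (not per phase), keeping cross-date comparability through the
   final step.

### Indicator definitions

- NDVI = (nir − red)/(nir + red).
- NDBSI = (SI + IBI)/2 with the bare-soil index
  SI = [(red + swir1) − (nir + green)] / [(red + swir1) + (nir + green)]
  and the built-up index IBI contrasting 2·swir1/(swir1 + nir) against
  nir/(nir + red) + green/(green + swir1). This is the canonical
  bare-soil/built-up pair of the RSEI literature; both sign behaviours
  (positive over bright bare soil and built-up land, negative over dense
  vegetation) are tested.
- Wet is the tasseled-cap moisture component, a fixed linear combination
  of the six reflectance bands with sensor-specific coefficients (TM and
  OLI/TIRS sets are built in and overridable).
- Lst uses the single-channel retrieval
  Lst = γ[(1/ε)(φ₁L + φ₂) + φ₃] + δ, γ = T²/(bL), δ = T − T²/b, where L is
  at-sensor thermal radiance, T brightness temperature, ε surface
  emissivity, and b = c₂/λ with c₂ = 14387.685 µm·K. The effective
  thermal wavelengths default to 11.457 µm (TM band 6) and 10.904 µm
  (Landsat 8 band 10) and can be overridden in configuration. The
  atmospheric functions are (φ₁, φ₂, φ₃)ᵀ = M·(w², w, 1)ᵀ with a 3×3
  per-sensor coefficient matrix and w the column water vapor in g·cm⁻².
  With ε = 1 and φ = (1, 0, 0) the retrieval reduces to Lst ≡ T exactly;
  this identity anchors the implementation.

### Data contract

All rasters of a computation share one grid (shape, geotransform, CRS);
nothing is resampled implicitly and mismatches raise. Validity is an
explicit boolean mask: cloud/quality screening is the caller's
responsibility (e.g. from QA bands), and a scene's mask is the conjunction
of all band masks plus any supplied QA mask. Reflectances outside [0, 1]
are clipped before index math (counted in the log); any zero denominator
masks the cell so downstream extrema fitting only sees finite values.
Degenerate normalization (max = min) maps to the shift constant c.

## Baselines

- **EI** = 0.35·BA + 0.25·NDVI + 0.15·WD + 0.15·(100 − LS) +
  0.10·(100 − PL) + EL on a 0–100 scale, with five-level classification
  (Excellent ≥ 75, Good ≥ 55, Medium ≥ 35, Inferior ≥ 20, else Poor;
  lower bounds closed). Biological abundance uses BA = (BI + HQ)/2 when a
  biodiversity index is available, else the habitat-quality-only path.
  The water-density sub-index is implemented as
  WD = (A_riv·S_riv + A_lak·S_lak + A_res·S_res)/(3S), the symmetric
  three-component mean of river length, water area and water resources —
  the published formula is typographically corrupted and this reading is
  the one consistent with its symbol list. All normalization coefficients
  (A_bio, A_veg, A_riv, …) are configuration inputs with no defaults, as
  they come from the assessment specification rather than the method.
  A 0–1 rescaled value (EI/100) is exposed for cross-model tables.
- **EQI** = Σᵢ LUAᵢ·LUCᵢ / SA over secondary LUCC classes; the 24-class
  weight table (paddy 0.30, dry land 0.25, woodland 0.95, urban 0.20, …)
  is built in and overridable. Computed as a weighted sum of per-class
  area fractions, which is exact for homogeneous regions.
- **RSEI** (single scene) = indicators → static per-scene min-max → PC1
  with the same sign convention → min-max rescale to [0, 1]. The sign
  repair is deliberately shared so the baseline differs from the composite
  only in normalization scope and temporal support.

## Synthetic data

The generator emulates a central-China agricultural mosaic at 30 m: a
winter-wheat plain (green November–May, stubble in high summer and
October), summer-corn fields (green June–September), deciduous forest
(leafy May–October), urban land, water and bare soil, on 12 monthly dates.
It is *index-first*: classes carry monthly NDVI/Wet/LST target
trajectories and bands are back-solved — nir and red from NDVI at a
class-specific brightness, both shortwave-infrared bands from the wetness
target, and the thermal pair by choosing the radiance at which the
single-channel operator is the identity so the brightness temperature can
be set to the LST target directly. NDVI, Wet and LST are hit exactly at
zero noise (except where a wetness target exceeds the physically reachable
range, as for water, where swir clips at 0); NDBSI is nonlinear in five
bands and is emergent, with its realized value recorded in the truth
table. Defaults: Gaussian band noise sd 0.01 reflectance, thermal noise
sd 0.3 K, cloud fraction 0.15 per date realized as one random rectangle
plus pixel pepper noise, 64×64 grid (128×128 in the recovery checks).

The truth table stores per-class per-date noiseless indicator means and an
intended annual ordering (forest > winter wheat > summer corn > bare >
urban) derived from the curves with an equal-weight proxy on min-max
normalized indicators. Water is excluded from the ordering: its extreme
wetness makes its rank sensitive to the aggregation weights, so it is not
a stable truth. What passing recovery tests show is that the pipeline
preserves a clearly separated ordering under modest noise and cloud
cover — not that it would resolve the much subtler contrasts, mixed
pixels, atmospheric residuals or sensor cross-calibration issues of real
Landsat archives. Clouds here are masks only; there is no cloud
*contamination* of retained pixels.

## Numerical choices

- Covariance (not correlation) PCA, since the four indicators share the
  [0, 1] scale after normalization; eigen-decomposition via a symmetric
  solver with eigenvalues clipped at zero to absorb round-off, and
  descending order enforced. Rank-0 input raises rather than returning an
  arbitrary direction.
- Covariance estimation subsamples uniformly at random to at most 2×10⁶
  valid cells; the seed is recorded in the model, making fits reproducible
  and memory-bounded.
- Extrema fitting is streaming and visit-order invariant; exact min/max
  (no percentile clipping) to match the transform's definition.
- Normalized values outside [min, max] — possible only when parameters
  came from a different scene set — clip to [c, c + d].
- Profile and point sampling use the nearest-cell rule (no interpolation)
  for reproducibility; sample statistics use the population (divide-by-n)
  standard deviation, recorded on the result object.
- GeoTIFF I/O goes through tifffile with ModelPixelScale/ModelTiepoint/
  GDAL_NODATA tags; values round-trip bit-for-bit on valid cells. The CRS
  travels as a string tag; no reprojection is offered anywhere.

## Open choices made here

- PCA scope defaults to per-date (one model per phase), matching the
  single-phase definition of the index; a global scope (one model over all
  dates pooled) is exposed as an explicit option.
- Seasons are meteorological (MAM/JJA/SON/DJF) with December assigned to
  the following year's winter.
- The minimum observation count for reporting a composite cell defaults
  to 1.
- Either surface or top-of-atmosphere reflectance is accepted; the choice
  is the caller's and travels with the manifest, since the indicator
  formulas are agnostic to it.

## Known limitations

- No cloud detection, gap-filling, temporal interpolation or reprojection;
  pixels frequently masked in the series are simply represented by fewer
  phases, which the observation-count raster makes visible.
- No outlier clamping of LST before normalization: a single extreme
  retained pixel stretches the global min-max map.
- The EI sub-indices require externally supplied statistics; nothing is
  estimated from imagery.
- Emissivity and water vapor are inputs; no emissivity-from-NDVI model is
  included.
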