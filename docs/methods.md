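# Methods

## The point-density proxy model

The package simulates nadir canopy radiance directly from voxelized LiDAR
point counts. The underlying assumption is that the number of returns in a
voxel is statistically proportional to the light-interacting surface area in
it, so the Beer–Lambert extinction term that would normally require a leaf
area density estimate can use the cumulative point count instead. Both the
incident path (sun) and the viewing path (satellite) are treated as vertical:
light enters each (i, j) column from the top, is attenuated by
exp(−α·P_sum) where P_sum is the total count strictly above the target voxel,
reflects from occupied voxels as a Lambertian surface (factor R/π), and is
attenuated again on the way up by exp(−β·P_sum). Column radiance is the sum
of the occupied voxels' contributions and is average-aggregated to the
satellite pixel grid.

Assumptions and their consequences:

- **Nadir-only geometry.** No solar zenith angle, no off-nadir view. The
  model therefore cannot represent directional effects; it is a diagnostic of
  vertical structure, not a general RT code.
- **Single scattering, scalar reflectance.** No multiple scattering, no
  wavelength dependence beyond R, no BRDF beyond the Lambertian factor.
- **α+β ridge.** Because both paths traverse the same cumulative count, the
  column radiance depends on (α, β) only through their sum. The calibration
  objective is flat along that ridge; the reported (α̂, β̂) is one grid point
  on it (ties break to the smallest values scanned first) and only α̂+β̂ is
  meaningful. Correlations, shifts and validation statistics are unaffected.
- **Occupied-voxel reflection.** A voxel with zero points has no scattering
  surface, so by default empty voxels contribute no radiance. The literal
  all-voxel sum — which would make column radiance depend on how much empty
  lattice sits above the canopy — is available via `reflect_empty=True` for
  comparison.
- **Exclusive cumulative count.** P_sum excludes the target voxel's own
  count: the attenuating material is what lies between the light source and
  the voxel.

## Parameters

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| Incident irradiance I | 1 | — | Correlation-based analysis; absolute scale cancels (I_sum linear in I). |
| Leaf reflectance R | 0.05 | — | Mean NIR reflectance of larch foliage spectra; also cancels in r. |
| α, β search range | 10⁻⁴ – 1 | point⁻¹ | Spans no-attenuation to full extinction within one voxel for typical counts. |
| Voxel size s | 0.5 | m | Common baseline that keeps per-voxel counts statistically stable for sparse sensors while preserving crown-scale structure. |
| Vertical layers | 10 | m | Canopy strata for median-count profiles (0–10, 10–20, … above minimum z). |
| CGR bin height | 0.5 | m | One voxel layer per bin at the default voxel size. |
| Satellite pixel | 10 | m | Sentinel-2-class NIR resolution. |
| Max shift / step | ±3 / 0.5 | m | Satellite geolocation accuracy (~2.5 m); step equals the fine cell. |
| Grid search | 17×17 coarse, 9×9 refine ×1 | — | Deterministic, monotone under refinement; a gradient method buys nothing on a 2-parameter ridge. |
| Validation | 70/30 split × 20 iterations | — | Stratified by observed-reflectance quartiles (plain random available). |

## Calibration and validation protocol

Each candidate (α, β) on the log grid is scored at its own best horizontal
shift (shift search nested inside the parameter objective); the alternative
order — fit at zero shift, adopt the shift afterwards — is available via
`SearchSpec(shift_inside=False)`. The shift search is an exhaustive
enumeration of the (2·max_shift/step+1)² offsets with deterministic
tie-breaking: smallest displacement first, then lexicographic. Aggregation of
a shifted fine map is an area-weighted mean over the fine cells each coarse
window covers; windows that fall partly off the fine extent use the covered
fraction, and windows with no coverage are undefined (NaN) and excluded from
correlations. Pearson correlation requires at least 3 masked-in finite pairs
and raises on zero variance rather than returning NaN.

The subsampling validation splits masked-in pixels into calibration (70%) and
held-out (30%) sets, stratified by observed-reflectance quartiles so both
sets span the dynamic range, refits (α, β) per iteration, and reports the
held-out r per iteration plus mean and standard deviation (NaN for a single
iteration). All randomness derives from `base_seed`, one child stream per
iteration, so summaries are bit-reproducible.

## Structural metrics

Voxelization uses half-open cells [lo, hi) with floor indexing everywhere
(a boundary point belongs to the higher-index cell); totals are conserved
(in-grid counts plus a reported out-of-bounds tally equal the input size).
When datasets are compared, one lattice is derived from the union bounding
box and reused for every cloud, merge and occupancy set — index-set metrics
are meaningless across different lattices, and `merge_grids` /
`coverage_gap_ratio` refuse mismatched ones, naming the offending field.

Layer medians are computed over **occupied** voxels (count ≥ 1) in each slab:
over a mostly-empty lattice the all-voxel median is identically zero and
carries no information. Slabs and CGR bins with no qualifying voxels are
reported as NaN, never 0. The CGR reference is the union of the supplied
datasets' occupancy (the all-merged model); an external reference — e.g. the
synthetic truth cloud — can be supplied instead for absolute-coverage
experiments, with the caveat that a sensor-derived reference measures
relative, not absolute, occlusion.

## The synthetic scene

The generator emulates the acquisition setting the metrics target, not any
particular instrument:

- **Stand**: a 150 × 70 m plot on a 3° planar slope; tree positions from a
  Poisson process at 730 stems/ha; heights 25–38 m with spheroidal crowns
  (radius 1.5–3.5 m, depth 6–12 m) above bare stems, plus a 400/ha shrub
  layer under 4 m. Crowns above bare stems produce the characteristic
  mid-canopy density minimum. Truth points are sampled on crown shells
  (6 pts/m²), in crown volumes (1.2 pts/m³), on stem cylinders (20 pts/m²)
  and on the terrain (2 pts/m²), Poisson-distributed per element.
- **Aerial scan**: nadir pulses on a 0.5 m grid keep the highest 5 candidate
  hits per footprint (a typical UAV return multiplicity; high-end sensors
  reach 32), so deep canopy and ground under dense crowns are occluded from
  above.
- **Ground scan**: a serpentine walking path (lines 25 m apart); each truth
  point survives with probability exp(−d/6 m) · exp(−0.15·n_below), d the
  horizontal distance to the path and n_below the count of truth points
  beneath it in its 0.5 m column. The two factors emulate range falloff and
  view-blocking by the canopy from below; their values were set so the scans
  exhibit the field-typical asymmetry — ground scans dense near the floor and
  largely blind to the upper canopy, aerial scans the reverse — which is the
  behaviour the structural metrics exist to detect.
- **Satellite stand-in**: the package's own forward model applied to the
  truth cloud at α\*=β\*=0.05 (strong enough that the signal is dominated by
  the upper canopy, as a nadir NIR signal is), mapped through a positive
  affine transform to a reflectance-like scale, plus i.i.d. Gaussian noise
  with sd = 0.6 × the signal's spatial sd by default. Provenance (seed,
  coefficients, noise, affine, shift) is recorded in a `TruthBundle`.

Because the observed raster is generated by the same forward model, recovery
experiments (zero-noise r → 1, planted shifts recovered, noise-attenuated r →
1/√(1+f²)) are internal-consistency checks of the pipeline — they demonstrate
correctness of the implementation, not physical validity on real forests.
The generator also omits real-data features: no SLAM drift or registration
error beyond isotropic coordinate noise, no beam divergence or waveform
effects, no species mixture or phenology, no atmospheric structure in the
image beyond white noise. Passing tests therefore say nothing about sensor
choice in an actual campaign; they say the metrics and the calibration behave
as specified on data whose ground truth is known exactly.

## Numerical choices

- Double precision throughout; attenuation via per-column exclusive
  cumulative sums from the top, so results are independent of traversal
  order.
- The calibration path evaluates radiance only at contributing voxels
  (a weighted histogram over precomputed cumulative counts); it agrees with
  the reference per-voxel path to float summation order and is tested against
  an independent triple loop at 1e−10.
- Outlier cleaning is a deterministic k-NN isolation rule (mean distance to
  k=5 neighbours exceeding global mean + 3 sd): an algorithmic stand-in for
  the manual removal practitioners apply; results on real data depend on
  (k, factor). Clouds of ≤ k points are returned unchanged with a warning.
- Degenerate inputs: empty clouds are legal everywhere except cleaning and
  calibration; all-empty grids, all-degenerate correlations and too-small
  pixel sets raise typed errors rather than propagating NaN.

## Problem sizes

The bundled scene produces ≈0.95 M truth points, ≈0.18 M aerial and ≈0.13 M
ground scan points on a 301 × 141 × 91 voxel lattice (0.5 m), a 16 × 8 pixel
satellite image, full calibrations in a few seconds and the complete
20-iteration validation in about a minute on one core — sizes chosen so the
whole pipeline, including the end-to-end checks, runs comfortably on a
laptop while keeping the plot at the field scale the defaults describe.

## Known limitations

- Only α+β is identifiable (see above); do not interpret the split.
- CGR against a sensor-derived reference is a relative completeness measure;
  a dataset can have CGR 0 and still miss structure no sensor saw.
- The shift search assumes a rigid translation; rotation or non-rigid
  georeferencing error is out of scope.
- LAS/LAZ reading requires the optional `laspy` dependency; the native
  interchange format is ASCII XYZ, and rasters are plain-text grids/CSV with
  TIFF export.
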