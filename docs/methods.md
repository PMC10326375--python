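# Methods

## Scope and model

`aggrekit` quantifies protein aggregates in three single-molecule microscopy
regimes:

1. **Diffraction-limited counting** (pull-down / liposome assays): aggregates
   appear as near-Gaussian spots of roughly 7–10 px diameter on a bright,
   slowly varying background. The detection model is a matched filter: white
   top-hat background suppression, convolution with a zero-sum Ricker wavelet
   (or unit-sum Gaussian), a global histogram threshold at mean + k·SD of the
   convolved image, a square opening to remove speckle, 8-connected labeling,
   and edge exclusion.
2. **Liposome permeabilization**: per-liposome calcium influx
   %Influx = (F_sample − F_blank)/(F_ionomycin − F_blank) × 100, with each F
   integrated over a radius-3-px disk (29 pixels) around peaks found in the
   ionomycin frame. Frames are stack averages registered by integer-pixel
   normalized cross-correlation.
3. **Super-resolution morphometrics**: localizations are grouped by DBSCAN
   (ε in nm, minPts, self-inclusive neighbour counting); per cluster we report
   localization count, rendered area, convex-hull area, covariance
   major-axis length (4·√λ_max) and eccentricity (√(1 − λ_min/λ_max)), and a
   skeleton length (render at 20 nm/px, thin, traverse by nearest-neighbour
   hops summing 1 px per axial and √2 px per diagonal step over all branches).

Two simulators generate the ground truth used by every validation test, so no
external data is needed.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| dot diameter range (DL sim) | 7–10 | px | typical diffraction-limited spot size |
| dot peak intensity | N(3000, 600) | counts | benchmark condition |
| baseline background | N(2000, 200) | counts | benchmark condition |
| maxima prominence | 1 | counts | resolvable-peak definition for the true count |
| detection threshold k | 2 | SD | Ricker-detector operating point |
| erosion size | 1 | px | removes isolated bright pixels |
| edge margin | 5 px (Ricker) / 2% per side (Gaussian) | | keeps only whole particles |
| Ricker σ | 1.5 | px | matched to 7–10 px dots |
| top-hat radius | 10 | px | larger than any expected spot radius |
| influx disk radius | 3 | px | liposome footprint |
| SR canvas / camera | 2500 / 500 | px | 5× super-resolution factor (20 vs 100 nm/px) |
| on-probability | 0.005 | per site per frame | sparse, PAINT-like frames |
| PSF σ (camera) | 1.1 | px | diffraction-limited spot width |
| fiducial intensity | 5× mean spot | | always-on landmarks |
| DBSCAN ε / minPts | 60 nm / 5 | | 3 render pixels; user-tunable |
| camera pixel size | 100 (sim) / 101.2 (instrument) | nm | always explicit in config |

## Numerical choices

- **True count by prominence.** Overlapping simulated dots merge into one
  intensity peak; the ground-truth count is therefore the number of local
  maxima with topographic prominence > 1 count, computed as 0-dimensional
  superlevel-set persistence with a union-find over intensity-sorted pixels
  (8-connectivity). Plateaus are broken in row-major scan order; a constant
  image has zero maxima. This equals the saddle-based prominence definition
  used by interactive maxima finders.
- **Dot rendering** uses σ = diameter/4, putting ≈95% of the Gaussian mass
  inside the nominal diameter.
- **Illumination gradient** is additive by default (amplitude
  0.25 × baseline mean, σ = image_size/2) and a multiplicative mean-1 Gaussian
  mask models beam-profile modulation in the SNR benchmarks; both are config.
- **Ricker kernel** is zero-lag normalized to integrate to exactly 0 on its
  discrete support (Gaussian to exactly 1); threshold statistics pool the full
  convolved-pixel histogram with no clipping of negative lobes.
- **Local background** for integrated intensities is the median of an annulus
  (inner radius = footprint radius + 2 px, width 3 px).
- **Registration** maximizes FFT cross-correlation over integer shifts within
  ±20 px; vacated edges are filled with the frame median; flat frames return
  shift (0, 0) rather than failing.
- **Localizer**: candidates above mean + 5·SD per frame, refined by
  least-squares 2-D Gaussian fit in a 7×7 window with an intensity-weighted
  centroid fallback; diverged fits are dropped.
- **Fiducials** are detected by persistence (≥90% frame occupancy within one
  camera pixel of a running anchor), not brightness, so real data need not
  follow the simulator's 5× intensity convention. Drift is the mean fiducial
  displacement from its first-frame position, smoothed with a 10-frame moving
  average. The drift model in the simulator is a cumulative random walk with
  per-frame steps of ±step or 0 on one random axis, and the exact trace is
  stored so correction can be validated against truth.
- **Skeleton idempotence.** Thinning is applied only when the mask contains a
  2×2 ON block; a mask that is already a unit-width chain is its own skeleton.
  Re-thinning such chains would clip the corner pixel of an L, breaking the
  hand-computable closed-form lengths. A single-pixel skeleton reports one
  render pixel (20 nm), the minimum resolvable size.
- **Eccentricity from point covariance**, not from rendered-mask moments:
  localizations are the primary data; the rendering exists only for area and
  skeletonization.
- **Degenerate inputs**: empty frames give empty particle sets (not errors);
  hulls of <3 non-collinear points have zero area; influx records whose
  denominator is below a 10-count floor are flagged invalid instead of
  divided; influx is not clipped to [0, 100] unless requested, because
  out-of-range values are meaningful noise.

## What the simulators do and do not emulate

The diffraction-limited simulator reproduces dot density, size and intensity
dispersion, baseline Gaussian noise and smooth illumination structure. It does
not model camera physics (EM gain, Poisson shot noise, pixel response), point
spread asymmetries or clustered/filamentous aggregates in the
diffraction-limited channel. The super-resolution simulator reproduces
per-site independent blinking, spot-intensity dispersion, fiducials and stage
drift, but not photophysical dwell-time kinetics, multi-emitter fitting
artifacts or 3-D defocus. Passing the validation grids therefore demonstrates
correctness of the analysis chain under idealized noise, not robustness to
every instrument artifact.

## Problem sizes

The counting validation grid uses nine 512×512 FOVs per condition, the
published FOV count. End-to-end length recovery uses eight structures per
condition and 1000-frame stacks — the stated stack length — at a 500×500
camera; three line-length settings (means 50, 100, 150 canvas px ≈ 1, 2, 3 µm)
bracket the 0.5–4 µm range.

## Known limitations

- Skeleton length systematically under-reports compact, round (dot-like)
  clusters: topological thinning of a convex blob collapses toward a point,
  so a ~80 nm round aggregate reads ~20–60 nm depending on boundary
  raggedness. The covariance major-axis length is the appropriate size
  measure for such clusters (it recovers disk diameters to ~10%); the length
  column is meaningful for elongated structures. Filament medians are
  recovered within a few percent at 1000 frames.
- The localizer is intentionally minimal (single-emitter LSQ); crowded frames
  bias positions. Tables from full-featured localization software can be
  ingested instead via the ThunderSTORM/GDSC dialects.
- The Gaussian-kernel ("connected-region") detector mode is a functional
  analogue of the corresponding Fiji plugin, not a port; per-particle size
  estimation differs in detail.
- Counting accuracy degrades when several dots merge within one PSF at high
  density; the Ricker mode is tuned for sparse-to-moderate densities.
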