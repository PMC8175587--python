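# Methods

## Problem and pipeline

Thinned and thickened regions interspersed across a retinal layer raise the
topographic complexity of its en-face thickness map. `retroughness`
quantifies that complexity as the grayscale box-counting fractal dimension
(FD) of the map and provides the cohort statistics needed to compare a
disease group against controls. The analysis chain is:

1. **Boundary surfaces.** Input is a per-eye stack of 11 surface elevation
   grids (inner limiting membrane to the outer boundary of the pigment
   epithelium) on the native OCT raster (512 A-scans x 128 B-scans, voxel
   11.7 x 46.9 x 3.5 um), with a validity mask and the foveal/papillary
   landmark positions. Left eyes are column-flipped to right-eye
   orientation so temporal/nasal anatomy is aligned across subjects.
2. **Thickness with tilt correction.** Raw thickness is the vertical gap
   `z_{k+1} - z_k`. Because the A-scan direction generally departs from the
   layer normal, the raw value overestimates true thickness; it is
   multiplied by `cos(theta) = 1 / sqrt(1 + |grad z_mid|^2)`, the tilt of
   the layer mid-surface `(z_k + z_{k+1})/2`. The gradient is taken by
   central differences in physical units (one-sided at borders, masked
   neighbours excluded, zero where no valid neighbour exists along an
   axis); using the mid-surface makes both bounding surfaces contribute
   symmetrically, and carrying the anisotropic pitches (11.7 vs 46.9 um)
   prevents a fourfold tilt distortion along the B-scan axis. A slab tilted
   rigidly (vertical gap inflated by `sec(theta)`) keeps its corrected
   thickness unchanged — the "flag" property.
3. **Spatial normalization.** Each map is moved, rotated and isotropically
   scaled so the fovea lands at the center of a canonical 512 x 512 grid and
   the maculopapillary axis is 4.377 mm long and tilted 6.766 degrees below
   horizontal (cohort-mean constants). The two landmark constraints
   determine the 4-dof similarity exactly (complex-linear fit, residual at
   machine precision). The canonical pitch is isotropic at 11.7 um/px — the
   finer native pitch — because box counting assumes comparable in-plane
   units; the 46.9 um row pitch is therefore upsampled bilinearly. An
   output pixel is valid only if all four contributing source pixels are
   valid, and out-of-coverage pixels are masked rather than erroneous.
4. **Central ROI.** Analysis is restricted to the fovea-centered square of
   2.555 mm, i.e. `floor(2555 / 11.7) = 218` px on a side (ties at the
   even-sided center resolved toward the lower index). FD requires the ROI
   to be fully valid; subjects with segmentation failures inside it are
   excluded and accounted for per stage.
5. **Fractal dimension.** Differential box counting (DBC): at spatial box
   size `s` the ROI is partitioned into `s x s` blocks; boxes of height
   `h = s G / M` (G = 256 gray levels, M = 218) are stacked over each block
   and the local count is `floor(max/h) - floor(min/h) + 1`. Two border
   conventions are implemented — *classic* (incomplete border blocks
   truncated) and *integer-ratio* (borders covered by shrunken blocks, every
   pixel counted) — and two thickness codings — *native depth* (gray =
   thickness / 3.5 um, rounded; invariant to whole-depth-step offsets) and
   *min-max 8-bit* (affine map of the observed range onto 0..255). FD is
   the OLS slope of `ln N_r` against `ln`(blocks per side) over the scale
   schedule.
6. **Cohort statistics.** Exact Mann-Whitney rank-sum comparison of
   per-subject mean FD (10 layers, and 9 neural layers excluding the
   pigment epithelium), paired t across per-layer group means with
   Shapiro-Wilk and Fisher variance-ratio checks, a one-sided Pearson
   correlation matrix (layer FDs vs MMSE, visual acuity, age), and a
   two-factor maximum-likelihood factor analysis with varimax rotation and
   KMO / Bartlett / determinant adequacy diagnostics.

## Numerical choices in the FD estimator

- **Scale schedule.** Near-geometric integers from 2 up to M/4 (for M = 218:
  2, 3, 4, 5, 8, 11, 15, 21, 30, 41, 54). All scheduled scales enter the
  fit by default. A denser schedule was found to shift the estimate
  without reducing its replicate variance.
- **Regression abscissa.** The fit uses `ln`(blocks per side) — `floor(M/s)`
  for the classic variant, `ceil(M/s)` for integer-ratio — which is the
  effective reciprocal scale of the covering actually counted. With this
  choice a constant map yields exactly collinear points of slope 2, so
  `FD(constant) = 2.000` holds to machine precision for every variant and
  coding; with the nominal `ln(M/s)` abscissa this exactness is impossible
  whenever `s` does not divide M (M = 218 has no useful divisors).
- **Range clipping.** A surface FD lies in [2, 3]; the reported `fd` is the
  slope clipped into that range (white noise can regress slightly above 3,
  near-smooth reliefs slightly below 2). The raw slope is kept in the
  result for diagnostics, along with per-scale counts and the fit R^2.
- **Gray range fixed at G = 256** for both codings so the box height is
  comparable across subjects; a per-map adaptive G would confound amplitude
  with roughness.
- **Box indexing** is floor-based with gray level 0 occupying box 0; the
  published DBC family varies on this point, so the choice is pinned by an
  independent brute-force block enumerator that the vectorised
  implementation must match exactly on randomized grids.
- **Degenerate inputs.** Constant maps under min-max coding encode to all
  zeros (FD exactly 2); empty valid sets, non-square ROIs, partially masked
  ROIs and schedules with fewer than 3 usable scales are rejected.

## Statistics

- **Exact Mann-Whitney.** The null distribution of U is enumerated by a
  counting recursion for combined n <= 50 without ties; with ties,
  mid-ranks are used and the p-value comes from an exhaustive permutation
  when `C(n, n1) <= 200 000`, else a seeded Monte-Carlo permutation. Both
  conventions are reported: U in [0, n1 n2] and the first-sample rank sum
  `W = U + n1 (n1 + 1) / 2`; W is the headline value because published
  rank-sum statistics at n = 19/24 exceed n1 n2 = 456.
- **One-sided directions** are fixed a priori: disease > control for FD;
  FD positively correlated with age and among layers, negatively with MMSE
  and visual acuity. Everything else is two-sided. No multiple-testing
  correction is applied anywhere; significance flags mark raw p < 0.05
  (a deliberate fidelity-over-optimality choice — interpret the correlation
  matrix accordingly).
- **Factor analysis** maximizes the likelihood by profiling loadings out of
  the uniquenesses (L-BFGS-B on log-uniquenesses, floor 0.005 with Heywood
  flagging), applies varimax, and sign-aligns columns. The sufficiency
  statistic uses Bartlett's correction `(n - 1 - (2p+5)/6 - 2k/3) F_min`
  with `df = ((p-k)^2 - p - k)/2` (26 for 10 variables, 53 for 13). The
  rotation is not identified by the published diagnostics alone; varimax is
  the standard orthogonal choice and is recorded as an assumption. The
  implementation is cross-checked against R's `stats::factanal` in the
  test suite.

## Synthetic cohort generator

The generator replaces clinical OCT data and defines the conditions under
which the pipeline is validated.

- **Anatomy.** Ten radial thickness profiles (periphery 18-68 um, total
  ~300 um) with a Gaussian foveal pit (sigma 500 um) thinning the inner
  six layers by 25-90%; a mild posterior-pole curvature on the inner
  limiting membrane. Surfaces are cumulative sums of non-negative layer
  thicknesses, which enforces the non-crossing invariant structurally.
- **Roughness.** Per-layer fractional Brownian fields by Fourier spectral
  synthesis (PSD ~ f^-(2H+2); theoretical surface FD = 3 - H), zero mean,
  unit RMS, scaled by a per-subject amplitude. Defaults: H = 0.5 and base
  amplitude 24 um, calibrated once so the *full pipeline* (including the
  smoothing introduced by bilinear resampling) lands group mean FDs near
  2.11 under the native-depth coding — the "slightly above 2" regime in
  which clinical layer maps are reported.
- **Latent structure.** Subject factor scores (F1, F2) load (3 um per unit
  score) onto two disjoint layer blocks — the inner/neural block (layers
  1-7, 10) and the photoreceptor-related outer-segment block (layers 8, 9)
  — plus 0.5 um independent noise, floored at zero. The simulated disease
  arm receives an additive 1.8 um amplitude increase, producing a mean-FD
  group gap of ~0.005-0.008.
- **Covariates.** MMSE (group means 23.4 / 28.4, clipped to the ranges
  [17, 29] / [25, 31]), decimal visual acuity and age are linear-Gaussian
  functions of the subject's mean amplitude deviation with fixed signs
  (cognition and acuity fall, age rises with roughness).
- **Determinism.** All randomness flows from one `SeedSequence`; identical
  seeds give bit-identical cohorts, and the subject-level draws are shared
  between the fully rendered path and the reduced-scale map path.

What the generator does *not* emulate: OCT speckle and intensity artifacts,
segmentation-failure geometry (beyond optional mask injection), vascular
shadows, the secondary ONL thickening at the fovea, and inter-layer
crosstalk of thickened regions. Passing tests therefore demonstrate the
correctness and calibration of the estimator and statistics under a
controlled roughness model, not clinical performance.

## Problem sizes used in validation

Replicate-heavy studies use the reduced-scale path (fovea-centered
isotropic maps, 48-64 px at 40 um/px, no resampling stage): 200 null
cohorts for type-I-error calibration of the one-sided group test, and 50
cohorts of n = 200 for two-factor block recovery. Estimator-oracle
equivalence uses 1000 random grids up to 16 x 16 against the brute-force
enumerator; Hurst monotonicity uses 10 seeds per H on 218 x 218 fields.
The full-resolution pipeline is exercised on the default 19 + 24 cohort.

## Known limitations

- The published integer-ratio DBC has several variants; equivalence with
  any specific binary is unverifiable, so clinical FD values can only be
  matched within tolerance, not exactly.
- Box-height coupling `h = s G / M` makes the native coding insensitive to
  perturbations smaller than one box on small grids; reduced-scale studies
  therefore use larger amplitudes or the min-max coding where appropriate.
- The adapter for the publicly deposited thickness dataset accepts a
  documented CSV layout and fails loudly on anything else; the deposited
  archive's actual dialect must be wired in against a real download.
- Exact FD reproduction of clinical tables would additionally require the
  per-subject clinical data; desk-scale checks are limited to statistics
  recomputable from published group means.
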