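# Methods

## The digital phantom

The object is a rectangular water box, 145 × 178 × 103 mm, holding twenty
cylindrical inserts of 24 mm diameter running the full 103 mm length,
arranged on a 4 × 5 in-plane lattice. Ground truth is rasterized at 1 mm
isotropic resolution. Each insert's material is abstracted into three
texture parameters:

* `base_intensity` — mean signal per sequence weighting (separate T1-like
  and T2-like columns, 60–478 arbitrary units across the twenty materials);
* `texture_amplitude` — SD of a zero-mean stationary random field added to
  the base (2–25 % of the material's weaker base intensity, so the truth
  stays strictly positive);
* `texture_correlation_length` — the Gaussian kernel scale of that field
  (1–5.75 mm, i.e. fine speckle through coarse blobs).

The texture field is white noise convolved with a Gaussian kernel and
rescaled to the requested SD; each insert draws from its own child seed of
the build seed. The parameter ladders are deterministic permutations chosen
so that the twenty materials are pairwise distinct and jointly span a wide
range of first-order and texture feature values; they are design choices of
this package, not measurements of any physical material set. The two
sequence weightings differ only in the base-intensity column — pulse-sequence
physics (TR/TE/flip angle) is deliberately out of scope.

## Scan simulation

A scan applies, in order: (1) a rigid translation (the test–retest
repositioning; uniform in ±1 mm per axis by default, no rotation);
(2) in-plane linear-interpolation resampling onto a matrix × matrix grid of
pixel size FOV/matrix centered on the phantom; (3) through-plane box
averaging into slices of the protocol thickness (the partial-volume model;
slice count = ceil(extent / thickness)); (4) magnitude noise, each voxel
replaced by |s + n_r + i·n_i| with n_r, n_i ~ N(0, σ_eff) and
σ_eff = noise_sigma / √NEX. Averaging NEX independent complex acquisitions
scales the complex noise SD by 1/√NEX exactly; at the inserts' SNR the
magnitude statistic is approximately Gaussian, while air voxels are
Rayleigh — both regimes keep the SD proportional to σ_eff, so the 1/√NEX
law holds everywhere and is verified by simulation in the tests.

Two "scanners" are configured (noise_sigma, intensity-scale) pairs
(`siemens`: σ = 4, scale 1.0; `philips`: σ = 5, scale 0.92); hardware
modeling beyond that is out of scope. With insert signals of 60–478 units,
σ = 4 puts the worst-case SNR above 10, well inside the Gaussian regime the
noise model assumes.

The default study grid is one-factor-at-a-time: NEX ∈ {1, 2, 3}, slice
thickness ∈ {2, 3, 4} mm, FOV ∈ {192, 256, 500} mm, each swept while the
others sit at their defaults (NEX 2, 3 mm, 256 mm), giving 7 distinct
conditions; every condition is acquired twice with repositioning between.
The acquisition matrix defaults to 192 so that every FOV setting keeps the
pixel at or above the 1 mm truth grid (resampling finer than the truth would
invent detail and is rejected as an error); the matrix is a regular protocol
field and can be swept as its own family when a finer truth grid is used.

## Regions of interest

Analysis ROIs are cylinders of 18 mm diameter (12 mm for the small-ROI
variant) and 100 mm height centered on each insert — comfortably inside the
24 mm insert, so the ROI never touches the partial-volume shell at the
insert wall. A voxel belongs to the ROI iff its center lies inside the
closed cylinder, evaluated on the scan grid of each acquisition, with the
ROI center following the repositioning shift (as a delineation drawn on the
scan would).

## The 76 features

Category sizes are 7 gradient-orientation-histogram, 22 GLCM, 11 GLRL,
31 intensity, 5 NGTD; column names carry a category prefix because a few
base names (Kurtosis, InterQuartileRange, Energy, Contrast, Variance) recur
across categories.

Shared conventions: gray levels are equal-width bins over the in-ROI
[min, max] with 64 levels by default (fixed bin *count*, so the same levels
are used across protocol settings of one ROI); entropies are log base 2 with
0·log 0 = 0; variance-style statistics use the sample (n−1) denominator;
percentiles use linear interpolation; skewness and kurtosis are population
moment ratios, kurtosis non-excess (3 for a normal), and both are defined
as 0 for a zero-variance sample.

* **GLCM** — accumulated per axial slice in 2D over the four distance-1
  offsets (0°, 45°, 90°, 135°), symmetrized, summed across slices and
  normalized once; pairs crossing the mask boundary are excluded. The 22
  statistics are the standard Haralick family. Degenerate rules: Correlation
  and both information measures of correlation return 0 when a marginal is
  degenerate.
* **GLRL** — maximal same-level runs per slice along the four 2D directions,
  broken at mask boundaries, summed over slices and directions. The 11
  Galloway statistics; RunPercentage divides the run count by the number of
  voxels traversed (the length-weighted run total), so it is 1 for fully
  fragmented texture.
* **NGTD** — per-slice 2D 8-neighborhoods; only voxels whose complete
  neighborhood lies in the mask contribute. The five Amadasun–King
  statistics, with Coarseness regularized as 1/(ε + Σpᵢsᵢ), ε = 10⁻⁶
  (capped at 1/ε for perfectly homogeneous regions), Contrast 0 when fewer
  than two levels occur, Busyness 0 when its denominator vanishes.
* **Intensity** — 17 global statistics on the raw in-ROI values (histogram
  statistics on the quantized levels), plus summaries (max/mean/median/min/SD
  as listed) of voxelwise local-entropy, local-range and local-SD maps over
  a 3 × 3 in-plane window restricted to in-mask voxels; local entropy uses
  the ROI's global quantization bins. The 3 × 3 window is the smallest
  standard choice; Energy is reported both raw and per-voxel (EnergyNorm)
  since the raw sum scales with ROI volume.
* **Gradient orientation histogram** — per-slice central-difference
  gradients; every in-mask voxel with nonzero gradient magnitude contributes
  its orientation angle in [0, 360). IQR, kurtosis and the two absolute
  deviations are computed on the pooled angles. "q PercentileArea" is defined
  here as the fraction of histogram bins (64 bins over the circle) needed to
  accumulate q % of the mass when bins are taken most-occupied first — a
  concentration measure that is 1/64 for a single edge direction and →1 for
  isotropic orientations. This reading of "percentile area" is a documented
  design choice; other readings exist.

Preprocessing arms reproduce the study's comparisons: raw intensities
(default), 3-sigma normalization (x ↦ (x − μ + 3σ)/(6σ) on the in-mask
values, clipped to [0, 1] — the mean maps to 0.5 and the mapping is invariant
under positive affine intensity changes; one published variant of the
method, chosen and documented rather than asserted as canonical), and
Butterworth low-pass smoothing (3D frequency-domain gain
1/(1 + (f/cutoff)^(2·order)), DC gain exactly 1; defaults order 2, cutoff
0.25 cycles/voxel — the typically unreported parameters are surfaced in
config).

## Robustness analysis

* **COV** is computed per (feature, ROI, parameter family) across the
  family's settings on the first scan, then averaged over the 20 ROIs to one
  value per (feature, family); categories use the boundary-inclusive rules
  quoted above. Features with negative means use |μ| in the denominator.
* **ICC(1,1)** pools rows over the whole grid: one row per (ROI × condition)
  pair, columns = the two repeated scans. A per-condition mode would also be
  defensible; pooling is the default because repeatability is asked of the
  whole protocol range at once. Features with no variance at all (identical
  everywhere) have undefined ICC and are reported as such rather than forced
  to a number.
* **Suitability** uses synthetic population bounds: per-feature mean and SD
  estimated from a reference feature table (by default the study's own
  first-scan values with the SD inflated ×2 to emulate a heterogeneous
  patient cohort), bounds = mean ± 2 SD, membership closed-interval. The
  percentage averages over features first, then conditions. The bounds stand
  in for a patient cohort that is not part of this package; absolute
  suitability percentages therefore characterize the synthetic setup, not
  any clinical population.
* **Heat map** — per-feature min–max rescale to [0, 1] (constant rows map to
  0), average-linkage hierarchical clustering of feature rows with Euclidean
  distance.

## What the generator does and does not emulate

The synthetic phantom reproduces the *mechanisms* that make radiomics
features protocol-dependent — resolution-dependent texture sampling,
partial-volume averaging, SNR scaling with NEX, repositioning
misregistration — under exactly known ground truth, which is what makes the
zero-noise recovery and noise-ordering tests meaningful. It does not emulate
pulse-sequence contrast physics, coil sensitivity profiles, bias fields,
gradient nonlinearity, k-space artifacts, or a living subject's motion and
flow; conclusions about *which specific* features are robust on a given
scanner require physical scans and should not be read off the synthetic
study. What transfers is the machinery: the extractor, the statistics, the
categorization, and the pipeline's behavior under controlled degradation.

## Numerical and design notes

* All randomness flows from explicit seeds through `numpy` `SeedSequence`
  spawning; per-stage seeds are derived, never reused, and a fixed master
  seed makes study outputs byte-identical.
* Feature extraction crops to the ROI bounding box (+2 voxels) before any
  computation; the default full study (7 conditions × 2 replicates × 20
  ROIs = 280 extractions) runs in about a minute on one CPU.
* The acceptance script's noise-law check uses 10⁴ background voxels; the
  test suite's noise sweep uses 3 noise levels × 20 test–retest replicates.
  These sizes keep Monte-Carlo error well below the margins being tested.
* Degenerate inputs fail loudly (constant ROI under normalization, masks
  with no valid texture pairs, all-identical ICC tables) instead of
  returning silent placeholders; the only capped quantities are the NGTD
  reciprocals, documented above.

## Known limitations

* 2D (per-slice) texture matrices are the fixed default; 3D offsets exist
  behind the config but are not exercised by the default study.
* The truth grid is 1 mm isotropic, so protocols with sub-millimeter pixels
  are rejected rather than simulated.
* ICC is the one-way single-measurement form only; two-way forms (ICC(2,1),
  ICC(3,1)) are out of scope, as are multiple-testing corrections.
* The supplementary "volume-corrected" GLCM variants some radiomics
  platforms offer are not implemented; the standard published formulas are
  used throughout.
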