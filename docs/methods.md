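# Methods

## Scope and data model

The pipeline quantifies dermal collagen organization on calibrated 2-D
grayscale rasters. A `CalibratedImage` couples intensities in [0, 1]
with a physical pixel size (µm/px for light microscopy, nm/px for TEM);
all physical outputs are obtained through that calibration, never from
pixel counts alone. Geometry is carried by `Polyline` objects —
ordered (row, col) point lists in pixel coordinates, 0-based.
Measurements are pooled by experimental condition (CT vs HA), timepoint
(24 vs 48 h) and dermis layer (papillary vs reticular), each group split
over two replicates.

## Amorphous-ECM fraction (light microscopy)

In an H&E section the fibrillar ECM takes up eosin (darker) while the
amorphous ground substance stays unstained (brighter). Within a dermal
ROI, pixels with intensity strictly above a threshold are classified
unstained; the statistic is the unstained percentage of the ROI,
`100·N_u/(N_u+N_s)`. Both counts are retained so the alternative
unstained/stained ratio is recoverable from the same result object. The
threshold is either supplied (`fixed`, modelling an expert-chosen
value) or computed by Otsu's between-class-variance criterion over the
ROI histogram (`otsu`, the default for synthetic data, where no expert
exists). RGB input is reduced to Rec. 601 luminance before
thresholding; no stain deconvolution is attempted. ROIs come from mask
files (real data) or cover the whole raster (synthetic fields are
all-dermis by construction); no automated dermis segmentation is done.

Key properties, enforced by tests: the percentage is non-increasing in
the threshold, invariant under strictly increasing intensity remappings
applied jointly to image and threshold, and the two counts always
partition the ROI.

## TEM morphometry

All profiles are sampled by bilinear interpolation at 0.5-px steps.
Edges are located by the half-depth criterion — the crossing of the
midpoint level between a local bright baseline and the dark minimum, a
full-width-at-half-minimum analogue — with sub-sample linear
interpolation at each crossing.

**Linearity (tortuosity) index.** Arc length of the centerline polyline
divided by the Euclidean distance between its endpoints; exactly 1 for
collinear points, undefined (error) for closed paths. Invariant under
rotation, translation and uniform scaling.

**Centerline tracing.** The study this emulates delineated bundles
manually; for synthetic images an automated stand-in thresholds the
dark phase (Otsu), opens with a 3×3 structuring element (speckle and
one-pixel bridges), closes with a disk of radius 3 px so that fibrils
separated by narrow bright gaps fuse into one solid band whose skeleton
follows the *bundle* axis, fills holes, skeletonizes, and takes the
longest skeleton path (double breadth-first search from the seed's
component). Raw 8-connected pixel chains overestimate arc length by up
to ~8% (staircase bias), and skeletons of wide bands end in diagonal
spurs about half the band width long; the path is therefore trimmed by
max(5% of its length, half the band width) at each end, Gaussian-
smoothed (σ = 3 px) and subsampled every 3rd point. On the synthetic
grid this keeps traced-vs-true linearity errors below ~2% (median
≈0.2%).

**Bundle thickness.** Nine perpendicular probes at evenly spaced
stations over the central 12–88% of the centerline arc length; each
probe is clipped symmetrically to the canvas, its background taken from
the probe tails, and the dark-band width measured between the first and
last half-depth crossings — internal bright gaps between fibrils do not
split the band. Probes without a sufficient dark band (contrast
< 0.12) or with a truncated band are dropped; more than half dropped is
an error. The returned value is the mean probe width in nm. Whether
thickness should be a single-site or along-bundle measure is not
prescribed by the emulated protocol; the mean-of-probes definition is
this package's choice and is stated here deliberately.

**Fibril size and interfibrillar distance.** On a transect crossing the
fibrils perpendicular to their axes (placed at the centerline
mid-station in cohort mode), fibril intervals are first detected as
runs below the global half-depth level; each edge is then refined at
the *local* half-depth level between the adjacent bright extremum and
that fibril's minimum. The local refinement matters for narrow gaps: a
global level biases a 5-nm gap at 2 nm/px by ~40%, the refined edges by
~15% (resolution-limited), and leaves ≥20-nm gaps essentially unbiased.
Diameters are interval widths; interfibrillar distance is the
edge-to-edge bright span between consecutive intervals — not
center-to-center, consistent with reporting distances much smaller than
fibril diameters. Intervals cut by the profile ends are discarded;
smoothing before detection is light (σ = 0.5 px) to limit broadening of
sub-resolution features. Per image, the central fibril and its adjacent
gap are probed at three centerline stations (35%, 50%, 65%) and the
medians over stations recorded — one diameter and one gap per image,
mirroring the one-measure-per-fibril sampling of the emulated protocol
while damping edge noise the way the thickness estimator's multiple
probes do (this halves the gap-recovery error).

**D-band periodicity.** The intensity profile along a fibril-axis
polyline is resampled evenly, linearly detrended, and autocorrelated;
the period is the lag of the first prominent positive autocorrelation
peak (prominence ≥ 0.05), refined by 3-point parabolic interpolation
and converted to nm. The dominant non-DC bin of the discrete spectrum
(also parabolically refined) serves as an independent consistency
check; disagreement beyond 10% flags the estimate low-confidence, and
the flag propagates into the measurement table. Profiles covering fewer
than five periods, or with no peak above the prominence floor, fail
explicitly. The autocorrelation peak is preferred over the spectral
peak for the returned value because it degrades more gracefully for
slightly anharmonic banding; affine intensity rescalings leave the
estimate unchanged.

## Statistics

Groups are summarized as mean ± SEM (SD with n−1 denominator over √n).
Pairwise comparisons are independent-samples tests: the compared groups
are distinct tissue measurements with no pairing key, so "paired
comparisons" is read as *pairwise group* comparisons. All variables use
the two-sided Mann–Whitney U test except D-band periodicity, which uses
the two-sample t-test (equal-variance Student by default; Welch
available). Mann–Whitney mode `auto` uses the exact null distribution
when min(n₁, n₂) ≤ 8 and the pooled sample is tie-free — enumeration is
then at most C(16, 8) = 12 870 labelings and fully verifiable by brute
force — and otherwise the normal approximation with tie and continuity
corrections. U + U′ = n₁n₂ always. Zero-variance t-test degeneracies
resolve by convention (equal means → p = 1; distinct means → p = 0,
flagged `degenerate`). Significance is p < 0.05 with no
multiple-testing correction, matching the uncorrected reporting the
pipeline emulates; one- vs two-sided and Student vs Welch are declared
defaults, not inferences.

The comparison plan per variable: CT vs HA within each layer ×
timepoint (4), 24 vs 48 h within each condition × layer (4), papillary
vs reticular within each condition × timepoint (4) — 12 comparisons per
variable, 72 for the full table. Missing groups skip their comparisons
with a log message.

## Synthetic data

The generator defines the study conditions; everything downstream is
validated against its exact ground truth.

**H&E fields.** A standard-normal raster is smoothed with a Gaussian of
σ = blob_length_scale / pixel_size (default 6 µm at 0.5 µm/px) and
thresholded at the quantile matching the target amorphous fraction —
organic blob shapes with an exactly known mask, realized fraction
pinned to the target within one pixel's probability mass (±1 pp
enforced). The stained/unstained phases are single-channel means (0.35
/ 0.85) with additive Gaussian noise (SD 0.05); the construction
enforces a ≥4·SD separation, so phase classification is nearly
noiseless and measured percentages track ground truth to well under
2 pp. H&E color is not simulated: the statistic reduces to a single
intensity threshold, and real RGB input is handled at the reader.
Default raster 256×256 px at 0.5 µm/px (the emulated study reports no
camera calibration; this is a configurable package choice).

**TEM fields.** A bundle of n parallel fibrils follows the sinusoid
y = A·sin(2πx/λ + φ); each fibril is a dark band of constant
perpendicular width (vertical offsets are corrected by the local slope
factor 1/√(1+y′²)) with a one-pixel linear edge ramp for sub-pixel
fidelity, separated by bright gaps, and modulated along the arc-length
coordinate with the D period. Sinusoids were chosen because the
linearity index has a cheap quadrature oracle: the stored true index is
arc length (dense trapezoid quadrature) over chord for the rendered
span, and tests verify it against independent quadrature to 0.1%.
Intensities: background 0.85, fibril base 0.40, D-band contrast as a
fraction of fibril intensity, additive noise SD 0.04; images are
quantized to 16 bits at generation so disk round trips are bit-exact.
Two pixel-size regimes stand in for the two magnifications of the
emulated protocol: 8 nm/px for bundle-scale images (thickness,
linearity) and 2 nm/px for fibril-scale and D-band images.

**Cohort design.** Eight groups (2×2×2), two replicates each; per
condition 40 LM images, 40 bundle-scale and 40 fibril-scale images (one
measurement each) and 100 single-fibril D-band images. Layer baselines:
papillary — amorphous 13.5%, 4 fibrils of 70 nm per bundle, linearity
1.055; reticular — amorphous 23%, 5 fibrils of 100 nm, linearity 1.04;
fibril-scale diameters 70/95 nm, gaps 16/18 nm, D period 62 nm
everywhere (below the canonical 67 nm, as in chemically fixed tissue).
Per-image biological variability: lognormal jitter with 10% CV on sizes,
25% CV on (LI − 1), Gaussian jitter of 1.2 pp on the amorphous target
and 1.2 nm on the D period; random phase per bundle. The treatment
design (`paper_effect`) modifies only the HA reticular-24h group:
amorphous 0.23 → 0.28, bundle fibril diameter and gap −10%, linearity
+5%, fibril-scale diameter +10%, gap −20%, D period unchanged. Bundle
amplitudes are solved from target linearity by bracketed root finding.
Extreme jitter draws that would overflow the canvas are capped
(amplitude first, then cross-section), so recorded ground truth always
reflects the rendered geometry. All per-image seeds derive from one
master seed via spawned `SeedSequence` keys and are recorded in the
manifest; identical (design, seed) pairs reproduce cohorts
byte-identically.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: epidermis, cells and appendages; staining
heterogeneity and RGB color; optics (no PSF), sectioning artifacts and
3-D structure; non-sinusoidal bundle paths; fibril diameter variation
within a bundle cross-section; spatial correlation between neighbouring
measurements. Results on real micrographs depend on annotation quality
(centerlines, transects) in a way the synthetic ground-truth sidecars
cannot capture.

## Validation studies and problem sizes

* **Estimator recovery** (`estimator_recovery_grid`): diameters
  {40, 80, 120} nm × gaps {5, 20, 40} nm × amplitudes {0, λ/16, λ/8} at
  both scales, periods {55, 61, 67} nm × amplitudes, default noise —
  117 measurements over 63 seeded images. Median relative errors:
  thickness ≈0.3%, diameter ≈0.8%, gap ≈2–4% (dominated by the 5-nm
  sub-resolution cells), linearity ≈0.2%, D period ≈0.3% — within the
  5% (2% for D period) bounds the tests assert.
* **Amorphous calibration** (`amorphous_recovery`): targets 0.10–0.30,
  27 images, per-image |measured − truth| far below 2 pp.
* **Type-I error** (`null_rejection_rate`): 200 replicate null
  measurement tables per test (lognormal populations, no group
  differences, 12 comparisons each); rejection rates ≈0.045–0.05,
  asserted within [0.02, 0.08]. Run at the measurement level because it
  calibrates the testing machinery, not the imaging chain.
* **Detection power** (`reticular_effect_replicates`): 12 replicate
  two-group cohorts at full sample sizes (n = 40; 100 for D band) with
  rasters scaled to half width; each affected variable must be
  significant in ≥90% of cohorts and D band non-significant in ≥90%.
  Twelve replicates keep the study inside a desktop run; the detection
  rates are high enough (≥11/12 observed) that the replicate count
  bounds the estimate, not the verdict.

## Numerical choices and degenerate inputs

Half-depth contrast floor 0.12 (below it a probe/profile reports "no
structure" rather than a noise-driven width); probes shorter than 16
samples are dropped; transect sampling step ≤ 1 px enforced; fibril
runs must span ≥ 2 samples; interval refinement falls back to
global-level edges if it would break ordering. Degenerate statistics
(constant ROI for Otsu, empty samples, n < 2 summaries, closed
polylines, constant axial profiles) raise explicit `ValueError`s with
actionable messages; cohort measurement converts per-image failures
into logged exclusions so a run continues and reports its n honestly.

## Known limitations

Gap estimates below ~3 pixels remain biased high by 10–20% even after
local-level refinement (resolution limit). The traced centerline is a
bundle-axis surrogate; on real images with touching bundles the
closing radius (3 px default) may fuse neighbours. The D-band
low-confidence flag is reported but flagged measurements are not
excluded from statistics. The duplicate structure is carried through
the tables but not modelled (no mixed effects), matching the emulated
analysis.
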