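# Methods

`nlomics` quantifies myocardial scar tissue from co-registered two-channel
non-linear optical microscopy: a second-harmonic-generation (SHG) channel
imaging fibrillar collagen and a two-photon-excited-fluorescence (TPEF)
channel imaging cardiomyocytes.  This note documents the models, the
numerical conventions, and the design choices, in the order the pipeline
applies them.

## Synthetic fibrous-tissue generator

Because no public two-channel cardiac dataset with per-frame class labels is
available, the package ships a generator whose presets encode the three
tissue phenotypes of healing infarcts:

* **muscle** — TPEF-dominant, long parallel myocyte bundles, a few short
  thin aligned collagen strands;
* **border** — numerous, longer and thicker interlaced collagen fibers among
  disordered myocardium;
* **fibrosis** — SHG-dominant mesh of thick, long, wavy collagen with sparse
  amorphous residual fluorescence.

**Fiber geometry.**  Per-fiber length and width are truncated-normal draws
(micrometres).  Orientation is axial (θ ≡ θ+180°) and uses the doubled-angle
construction: a von Mises draw on the full circle at concentration κ around
the doubled mean, halved back to [0°, 180°).  κ = 0 is isotropic; large κ
concentrates orientations at the mean.  Waviness w ∈ [0, 1] bends the
centerline into a one-to-two-period sinusoid whose amplitude grows with w,
so straightness (chord / arc length) decreases monotonically in w; w = 0 is
a straight line.

**Rendering and compositing.**  Each fiber is an additive ridge whose
cross-section is approximately Gaussian with FWHM equal to the fiber width;
TPEF myocyte bundles use a saturated flat-top ("plateau") cross-section
instead, because myocyte fluorescence fills the bundle rather than peaking
on a centerline.  Both channels then pass through a tissue-level soft
saturation, `scale · tanh(sum / scale)`: overlapping structures do not
double their emission (fluorophore density saturates; crossing collagen
fibers are not mutually phase-matched; detector range is finite).  This
compositing choice matters downstream — it makes the channel histograms
bimodal (background vs. tissue plateau), which is what lets
maximum-entropy thresholds land in the valley between the modes and makes
the segmented-pixel counts track physical fiber abundance.  The fibrosis
preset adds a smooth nonnegative haze (`tpef_diffuse_level`) emulating
amorphous residual fluorescence: it raises the TPEF mean without creating
segmentable structure.

**Noise.**  Poisson shot noise on the rendered signal plus additive
Gaussian read noise (sd 3 counts), then rounding and clipping into a 16-bit
container; preset intensities occupy roughly a 10-bit signal range.  No
optical point-spread function or depth attenuation is modelled.

**Study layout.**  `generate_dataset` mirrors the acquisition: per class a
set of regions of interest (ROIs), each a depth stack of frames; ROI-level
log-normal jitter (sd 0.08) of counts, sizes and intensities plus a random
per-ROI global orientation offset create within-class batch structure; ROIs
are partitioned into two pseudo-subjects so train/test splits can segregate
subjects, as the study design requires.  Everything is deterministic given
the seed (per-frame seeds derive from a `SeedSequence` tree).

**Preset calibration.**  Preset intensities were calibrated once so the
collagen intensity ratio C_I lands near 0.1 for muscle and near 0.3 for the
pathological classes, and so the class contrasts in C_S, fiber morphology
and orientation point in the directions reported for real infarcted
myocardium.  The presets are configuration, not constants.

**What passing tests do and do not show.**  The generator reproduces the
*ordinal* structure of the real classes (which class has more, thicker,
longer, more disordered collagen), not calibrated absolute feature values;
real tissue adds depth-dependent attenuation, spatially varying background,
and richer texture.  End-to-end classification results on synthetic data
are an artifact benchmark demonstrating that the pipeline is lossless
enough to separate well-separated classes — they are not predictions of
accuracy on real tissue.

## Image I/O and requantization

Stacks are interleaved multi-page TIFFs (SHG page then TPEF page per depth
plane) with channel order declared in metadata.  Stack-level requantization
to 8 or 16 bits is a single linear map per modality over the whole stack
(`round((v − min)/(max − min) · (2^bits − 1))`, rounding half away from
zero; a constant stack maps to zero).  Min/max are taken per channel over
the entire ROI stack, never per frame, so relative intensities across depth
survive.

## Preprocessing

**Frangi vesselness.**  Per scale s ∈ {1.8, 4.9, 8} px (interpreted as the
Gaussian standard deviations of the derivative kernels; a diameter/2
interpretation is one configuration flag away), the gamma-normalized
Hessian (entries × s²) gives eigenvalues |λ1| ≤ |λ2|, blobness
R_b = λ1/λ2 and structure norm S = √(λ1²+λ2²); the bright-ridge response is
`exp(−R_b²/2β²)(1 − exp(−S²/2c²))` with β = 0.5, zero where λ2 > 0, c auto
set to half the maximum S of the scale, and the output is the maximum over
scales.  Two numerical guards: the truncated second-derivative kernels of
`scipy.ndimage.gaussian_filter` do not sum exactly to zero, so their
response to a constant (kernel sum × local mean) is subtracted — without
this a flat image acquires a spurious uniform Hessian of order 5·10⁻⁴ of
its intensity which the auto-c rule would amplify to an O(1) response; and
a scale whose maximum S is numerically zero is skipped outright.

**Entropy thresholds.**  `max_entropy_threshold` maximizes the sum of Rényi
entropies of the below/above class distributions over all candidate levels
(order α → 1 recovers the Kapur maximum-entropy criterion; upper-tail sums
are accumulated from the right to avoid cancellation at α ≠ 1).
`li_threshold` iterates the Li–Lee minimum-cross-entropy fixed point on the
histogram with levels shifted so the lowest occupied level maps to 1 (logs
need positive support; the shift also makes the threshold exactly
shift-equivariant), then refines over a ±2 window on the cross-entropy
objective so the returned integer threshold attains the discrete optimum.
On bimodal histograms several thresholds inside an empty gap induce the
same partition; objective values, not bin indices, are the meaningful
output.  Foreground is always `value > threshold`.

**Stack segmentation.**  SHG: Frangi per frame → 16-bit stack rescale →
pooled stack threshold → binary.  TPEF: 8-bit stack rescale → pooled stack
threshold → binary.  Stack-level thresholds of deep images are computed on
a 256-bin histogram spanning the observed range and mapped back to
intensity, matching the behaviour of the reference Auto-Threshold tooling
and keeping the entropy criterion stable when a full-depth 16-bit histogram
would be sparsely occupied.  A structureless (noise-only) stack still
yields a small nonzero foreground fraction — an entropy criterion always
splits the pooled histogram — which plateaus around 3–4% at the study's
stack density; segmentation results on frames without real structure
should be interpreted accordingly.

**Masks, binning, renormalization.**  The radiomics foreground mask is the
OR of per-channel Li thresholds.  Binning is exact block averaging (4×4 by
default; shapes must divide, no padding).  Background renormalization
divides a frame by its mean background (pixels outside the mask), making
the result invariant to global intensity scaling and idempotent.

## Conventional features (16 per frame)

Collagen amount: C_I = mean(SHG)/(mean(SHG)+mean(TPEF)) over the full
frame; C_S = N_SHG/(N_SHG+N_TPEF) over segmented pixels.  Morphology: the
fiber tracer skeletonizes the collagen segmentation, splits the skeleton at
junctions, orders branches into polylines and re-merges branches whose
continuation turn angle is below 30° (configurable), pruning fibers shorter
than 15 px; per fiber it reports arc length (µm), width (µm, derived from
the mean distance-transform value along the centerline minus the one-pixel
bias of measuring to background pixel centers), straightness (chord/arc)
and the chord's axial angle.  The per-image summary is the count plus
mean/sd (population) of length, width and straightness; an empty trace
yields count 0 and NaN moments.  This tracer is a skeleton-based method
producing the same per-fiber quantities as curvelet-based fiber extraction;
it is not a port of that algorithm.

Orientation: three normalized 180-bin (1°) axial histograms per frame — the
Fourier-spectrum directionality of each channel (windowed power spectrum,
polar-binned, mapped to structure angle = spectral angle + 90°, CCW from
the x-axis) and the traced-fiber angle histogram.  Each is summarized by
the mean vector accumulated directly on [0, π):

    X̄ = Σ f(θ) cos θ,  Ȳ = Σ f(θ) sin θ,  MVL = √(X̄² + Ȳ²),

deliberately *without* the classical doubled-angle transform, to match the
statistic as defined; the price is that a uniform histogram gives
MVL = 2/π ≈ 0.6366 rather than 0, and exact rotation-equivariance holds
only while no mass wraps past 180°.  A doubled-angle MVL is available as a
separate diagnostic.  The range R is the shortest circularly contiguous run
of bins whose weight strictly exceeds 1/2 (exhaustive scan; ties resolve to
the shorter arc, then the smaller start angle; a delta histogram gives one
bin = π/180, a uniform one gives 91 bins).  The mean angle is the atan2 of
(Ȳ, X̄) mapped to [0, π), and the SHG–TPEF mismatch is the axial distance
min(d, π − d) ∈ [0, π/2].

## Radiomics panel

On 128×128, 8-bit, background-renormalized images (one linear requantization
per modality over the whole dataset) with the OR foreground mask, the panel
computes per modality: intensity statistics, local intensity peak (disk
radius 3 px around the global maximum), discrete histogram features
(including the histogram-gradient family), intensity-volume-histogram
fractions on the observed range, 2-D mask morphology (area standing in for
volume, perimeter for surface; `morph.com` is the geometric-vs-intensity
centroid shift), and the five texture families GLCM, GLRLM, GLSZM, NGTDM
and NGLDM.  Conventions: a single image is one slice; GLCM/GLRLM compute
features per direction over the four 2-D directions and average them;
discretization is fixed bin size 1 on levels 0..255; texture levels are
1-based (`level + 1`) so low/high-gray-level weightings are well defined;
GLSZM zones are 8-connected; NGTDM neighbourhood means use masked
8-neighbours only, excluding pixels with none; NGLDM dependence is the
count of masked 8-neighbours within coarseness α = 0 of the center, stored
1-based.  Features undefined on degenerate input (e.g. GLCM correlation on
a single-level region) are NaN and listed in a flag set, never silently
zeroed.  Every feature is keyed `<MODALITY>::<Family>::<name>` and every
one is checked against an independent brute-force implementation in the
test suite.

## Harmonization and statistics

The KDE overlap of a feature is ∫ min(f_train, f_test) over a grid spanning
both samples padded by five bandwidths (1024 points; wide enough that
identical samples give 1 within 10⁻⁶).  Bandwidths come from a
diffusion-style (improved Sheather–Jones) fixed point with a Silverman
fallback.  Screening keeps a feature iff its overlap ≥ threshold (default
0.75, applied to radiomic features; conventional features are not screened
by default); features with more than 20% missing values are dropped with a
logged reason.  Group tests are the tie-corrected Kruskal–Wallis (k classes,
chi-square p; all-identical data returns H = 0, p = 1) and the two-sided
Wilcoxon rank-sum (exact, tie-safe enumeration of all C(n, n_a) labelings
for n ≤ 12, otherwise normal approximation with tie correction), both at
the raw 0.05 level with no multiple-testing correction by default (a
Benjamini–Hochberg helper exists, off by default).  The
radiomic-vs-conventional association matrix is pairwise-complete Pearson r.

## Classification protocol

A transparent stand-in for the automated ensemble service, with every
preprocessing step inside the fold: Monte-Carlo train/validate splits
(default 100 folds; the end-to-end benchmark uses 20) draw a class-balanced
validate set of ⌊0.2·N/k⌋ per class (minimum 1) and leave the imbalanced
remainder for training.  Per fold: range normalization to [0, 1] from train
statistics; redundancy reduction dropping the later of any feature pair
with |r| > 0.95; univariate selection of the top 20 features by
Kruskal–Wallis H; minority upsampling to the majority count by convex
interpolation of same-class pairs (synthetic rows flagged; singletons are
duplicated with jitter under a warning); three heterogeneous base learners
(logistic regression, random forest, k-nearest-neighbours with k adapted to
fold size) stacked under a logistic meta-learner trained on out-of-fold
class probabilities.  Per-feature ranking weights are permutation
importances of the full stack on the fold's validate split, clipped at
zero and normalized to sum 1 (dropped features get 0), reported as
mean ± sd across folds.  Held-out inference aggregates the fold models by
per-case majority vote; reports include the k×k confusion matrix, accuracy,
per-class sensitivity, and the collapse of {border, fibrosis} into one
pathological class with binary accuracy and specificity.

## Problem sizes and determinism

The default end-to-end study is 3 classes × 2 ROIs (one per pseudo-subject)
× 15 frames at 512×512 px, 20 Monte-Carlo folds — chosen so the full
pipeline, including segmentation, tracing and both radiomics panels, runs
in about two minutes on one CPU.  Unit and recovery tests use 128–256 px
frames.  All randomness flows from explicit integer seeds; identical
configurations produce byte-identical feature tables, and the run directory
records the configuration and its hash.

## Known limitations

The fiber tracer merges crossings greedily by turn angle and can split very
wavy fibers at sharp junction clusters; widths are footprint-based and
depend on the segmentation threshold; the Fourier directionality estimate
has ±1–2° bin quantization; the non-doubled MVL convention compresses the
dynamic range at the isotropic end (floor ≈ 0.64); entropy thresholds on
structureless stacks retain a few percent foreground; and synthetic-data
accuracies should not be read as expected performance on real tissue.
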