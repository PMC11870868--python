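# Methods

## Problem

Total mesorectal excision (TME), the standard resection for rectal
cancer, is substantially harder in a narrow, deep pelvis, and several
bony-pelvis dimensions predict operative difficulty and outcome.
Those dimensions can be measured on the sagittal T2-weighted MRI every
rectal-cancer patient already receives, but manual pelvimetry is slow
enough that it is rarely done. This package automates it: five
anatomical landmarks are localized in the 3D volume, four clinically
predictive dimensions are derived from them, and the automated
measurements are compared against manual annotation with a full
agreement battery.

## Landmarks and dimensions

The five landmarks, annotated near the sagittal midline but treated as
unconstrained 3D points in physical millimetre space, are the
promontorium (A), the S3 vertebra (B), the coccyx (C), and the dorsal
(D) and cranial (E) aspects of the os pubis. From them:

* pelvic inlet  = |A − E|
* pelvic outlet = |C − D|
* pelvic depth  = |A − C|
* sacral angulation = angle at B between rays B→A and B→C

All geometry is computed in millimetres, never in voxel units, because
clinical voxels are strongly anisotropic (~0.67 × 0.67 × 4.3 mm). The
angle uses the arccos of the clamped normalized dot product, so
collinear configurations cannot fall outside the arccos domain through
rounding. Missing landmarks propagate as flagged-unmeasurable
dimensions rather than errors, keeping partial predictions reportable.
Treating the coordinates as fully 3D (rather than projecting onto a
mid-sagittal plane) is a deliberate choice; the out-of-plane component
of real annotations is small and the 3D distance is never smaller than
the in-plane one.

## Preprocessing

Volumes are trilinearly resampled onto a reference grid whose spacing
defaults to the dataset-mean clinical voxel size (0.67 × 0.67 ×
4.3 mm). The output shape is `round(shape · spacing / reference)` per
axis (minimum 2), which preserves the physical extent to within one
output voxel; the origin and orientation are kept, so resampling never
moves physical coordinates — the property the whole pipeline relies on
when predictions made on the resampled grid are reported in the
original frame. Voxel indices are 0-based and refer to voxel centers.

Intensities are normalized per volume by mapping two percentiles of
the intensity distribution (defaults: 1st → 0, 99th → 1) affinely,
with optional clipping to [0, 1]. The percentile values are
configuration, not constants, since acquisition protocols differ.
Clipping is the default for clinical-style input; the phantom-study
preset disables it because the phantoms encode landmark identity
partly in blob intensity, and clipping at the 99th percentile would
flatten the brightest blobs to a common value.

## Heatmap regression

Rather than regressing coordinates, each landmark is represented by a
Gaussian heatmap whose peak marks the position (standard deviation 5
voxels by default, isotropic in index space on the resampled grid and
therefore anisotropic in millimetres; a millimetre-space sigma is
available behind a flag). Targets are built analytically from the
closed-form separable Gaussian and peak-normalized to 1 — equivalent
to filtering a delta image up to boundary truncation, which the test
suite uses as an independent oracle. Decoding takes the per-channel
argmax voxel, converts it to millimetres, and reports the peak value
as a confidence score; exact ties break deterministically to the
lowest lexicographic voxel index and are flagged. Channels whose peak
does not exceed a configurable floor decode as missing. There is no
sub-voxel refinement: plain argmax quantizes each axis to half a voxel
at worst, which at the reference spacing is small against the
annotation noise.

The peak confidence exists because a known failure mode — a dark
banding artifact across the pubic bone — produces flat, low heatmaps;
thresholding the peak lets a caller flag such volumes for manual
review instead of silently reporting a wrong dimension.

## The network

The localizer is an encoder–decoder with skip connections (a small 3D
U-Net): per level two convolutions, max-pooling that halves the
in-plane axes but pools the slice axis only while its nominal size
stays ≥ 8 (the clinical volumes are only ~16 slices deep),
nearest-neighbour upsampling, skip concatenation, and a final 1×1×1
projection to five channels. Convolutions are factorized into a
(3,3,1) in-plane pass followed by a (1,1,3) through-slice pass; this
quarters the arithmetic of a full 3×3×3 kernel while covering a
comparable physical extent per pass, since voxels are ~6× thicker
through-slice than in-plane. Rectifiers are leaky (slope 0.01) so an
aggressive early step cannot permanently silence a unit, and the final
projection is zero-initialized so optimization starts from the
empty-heatmap prediction — without it, early training can commit
individual output channels to the wrong blob and spend most of the
budget undoing the mistake. The network
and its training loop are implemented directly on numpy (im2col +
BLAS matmul with hand-derived backpropagation, verified against
finite differences in float64); the implementation is deliberately
minimal and CPU-oriented.

Training minimizes mean-squared error between predicted and target
heatmaps on randomly sampled patches. Patch sampling is
landmark-biased (default 70–80% of patches centered near a randomly
chosen landmark, jittered by up to a quarter patch; the rest uniform)
so the rare foreground signal appears in most batches; border patches
are zero-padded. Optimization uses Adam with an optional
multiplicative per-epoch learning-rate decay. After each epoch a
validation loss is computed on deterministic landmark-centered
patches; training stops when it has not improved for the configured
patience, and the parameters of the best-validation epoch are
returned. All randomness flows through one seeded generator, so two
runs with the same configuration are bit-identical.

Two configuration regimes exist. The default mirrors the
clinical-scale regime (learning rate 1e-4, batch 32, patch
128 × 128 × 16, up to 500 epochs with patience 50); it is what a GPU
user would start from and is not exercised by the test suite. The
`tiny` preset (learning rate 3e-3 with 0.87 decay, batch 4, patch
16 × 16 × 8, depth 1, 8 base channels, 12 epochs × 400 steps) is the
CPU regime used for all phantom studies; its higher learning rate and
small patches reflect the far easier synthetic task.

Inference tiles the preprocessed volume with overlapping windows and
mean-blends the logits (a single padded whole-volume window by
default, since phantom-scale volumes fit in memory), then decodes.
Because the resampled grid shares the original origin and orientation,
decoded coordinates live in the original volume's physical frame.

## Phantoms

No clinical data ships with the package, so a phantom generator
provides volumes with known ground truth. Each phantom is an
anisotropic grid (default 96 × 96 × 16 at 1.5 × 1.5 × 4.3 mm — 
in-plane-coarser than clinical so CPU training stays in minutes, with
a clinical-spacing preset available) containing background Gaussian
noise (SD 0.05) and five bright Gaussian blobs at landmark positions.

Landmark geometry is constructed, not rejection-sampled from scratch:
the sacral chord A–C is drawn at the sampled pelvic depth, B is placed
off the chord at exactly the sampled sacral angle, E at the sampled
inlet distance, and D at the sampled outlet distance from C, slightly
rotated off the C–E line so the two pubic blobs stay ≥ 20 mm apart.
Points get a small out-of-plane jitter (SD 1 mm), are translated to
fit the grid with a blob-sized margin, and the draw is rejected if any
derived dimension leaves its configured range. Ranges (inlet
100–140 mm, depth 90–130 mm, outlet 70–110 mm, angle 140–175°) bracket
adult pelvic anatomy.

Each blob has a distinct radius (12 mm down to 6 mm from A to E,
profile 2.0–1.0× a 6 mm base) and a distinct intensity (profile 1.6,
1.3, 1.0, 0.75, 0.5). The two cues together make channel identity
locally decodable — a convolutional network can read spatial scale and
absolute peak intensity from a small patch — and make a
channel-ordering bug visible as a systematic landmark swap. Radius
runs opposite to contrast so the dimmest blob is also the sharpest,
which equalizes peak-localization precision across channels, and the
intensity spread is wide (adjacent peaks differ by several noise
standard deviations) because channels whose blobs sit mid-ranked in
both cues are otherwise the last to be disambiguated. On top of the
per-landmark profiles, each phantom draws a global blob-amplitude
scale (uniform on 0.8–1.25), per-landmark contrast jitter (lognormal,
SD 0.05) and per-landmark size jitter (lognormal, SD 0.04), emulating
the scanner-, protocol- and anatomy-dependent variation of a
multi-center cohort; an in-plane elliptical-stretch knob exists for
harder non-spherical landmarks but is off by default. An optional
banding artifact attenuates a configurable slab (default 10×
attenuation over a 25 mm band centered between D and E), reproducing
the occlusion failure mode.

Cohorts carry a multi-institute structure (per-institute patient
counts), per-patient sub-seeded generation, and an optional simulated
second observer whose annotations are the reference jittered by
isotropic Gaussian noise — at SD σ the expected landmark distance is
σ·2·√(2/π) (chi distribution with 3 degrees of freedom), which the
tests verify against a Monte-Carlo oracle.

What the phantoms do *not* model: anatomy other than the five
landmarks, soft tissue and bone texture, bias fields, scanner
differences between institutes, or annotation ambiguity correlated
with image content. Passing the phantom studies therefore shows that
the pipeline machinery (preprocessing, target generation, training,
decoding, bookkeeping, statistics) is correct and that the network can
learn localizable structure — not that clinical-grade accuracy would
be reached on real MRI.

## Evaluation protocol

Localization error is the per-landmark Euclidean distance (mm) between
prediction and reference, summarized as MAE ± SD (sample SD, n−1
throughout). Errors are tabulated per institute × per landmark with a
pooled "All" row and a pooled "Mean" column.

Dimension agreement reports, per dimension: MAE ± SD of the absolute
differences; R² computed as the coefficient of determination
1 − SS_res/SS_tot about the reference mean (not the square of Pearson
r — the two differ under bias); Spearman rank correlation; bias,
defined as mean(reference − predicted); limits of agreement
bias ± 1.96·SD(differences); the indices of pairs strictly outside the
LoA; and R² recomputed on the retained pairs after excluding them.
The LoA are computed once from the full sample. Constant reference
values make R² undefined and are flagged rather than silently
reported.

Inter-observer variability pools per-landmark distances between the
two observers' annotations over all dual-annotated patients and
summarizes them as MAE ± SD.

The center-stratified k-fold split shuffles each institute's patients
with a generator seeded by the global seed plus a CRC-32 hash of the
institute label (adding an institute never reshuffles the others) and
deals them into k folds whose per-institute sizes differ by at most
one. Institutes' remainder patients go to the currently smallest
pooled folds, so pooled fold sizes also differ by at most one; on an
8-institute profile totalling 1707 patients this yields test folds of
{342, 342, 341, 341, 341} and the 80/20 = 1365/342 split for the
largest folds. Every patient appears in exactly one test fold.
Institutes smaller than k are flagged and folded best-effort. The
partition property — not any particular printed pair of fold sizes —
is the contract.

## Parameter-recovery study

The end-to-end check trains the tiny U-Net on seeded phantom cohorts
and asks whether the full pipeline recovers the landmarks it planted.
Each replicate generates 25 phantoms (20-phantom training pool, 5 held
out), trains on a prefix of the pool (80/20 internal train/validation
split), and measures the mean landmark error on the held-out phantoms.
Three seeded replicates are averaged, at training-pool sizes 5 and 20.
Each size trains for the same number of passes over its pool — the
step budget scales with the subset size, the standard learning-curve
protocol — so the comparison varies data, not per-volume exposure;
under a fixed total-step budget the small subset would simply be
trained longer per volume and the curve would flatten. Two properties
are expected: the 20-phantom model's mean error stays below twice the
in-plane phantom spacing (3 mm at the default 1.5 mm spacing — roughly
the argmax quantization floor plus one in-plane voxel of model error),
and the averaged error at 5 training phantoms exceeds the averaged
error at 20. Problem sizes (cohort of 25, up to 4800 training steps of
batch 4) keep a replicate under two minutes on one CPU core and the
whole study around seven minutes.

## Numerical choices and edge cases

* Sample (n−1) standard deviations everywhere; a single value reports
  SD 0.
* Argmax ties: lowest lexicographic voxel index, flagged.
* Degenerate percentile window (constant volume): all-zero output.
* Resampling interpolation: trilinear, edge-replicating at borders;
  a constant volume stays exactly constant.
* Angle at a zero-length ray: error, not NaN.
* Agreement needs ≥ 3 pairs; outlier-excluded R² needs ≥ 2 retained.
* Checkpoints embed config, seed, history and selected epoch.
* Seeds derived from a master seed stay below 2³¹.

## Known limitations

* The numpy network is single-threaded BLAS-bound; the clinical-scale
  configuration is impractical without a GPU framework backend.
* No data augmentation, ensembling, or sub-voxel peak refinement.
* The phantom task is far easier than clinical landmark detection;
  accuracy numbers from the recovery study do not transfer to
  patients.
* Heatmap sigma in voxel units means the physical target shape changes
  if the reference spacing changes.
* Bland–Altman outlier exclusion assumes approximately Gaussian
  differences; with heavy-tailed contamination the LoA themselves are
  inflated.
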