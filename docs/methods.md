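# Methods

## Problem and pipeline

`spherotype` classifies single cells in 3D confocal z-stacks of mixed tumor
spheroids (tumor cells + fibroblasts co-cultured ~1:1 in a fibrin gel) using
only channels available without cell-type-specific staining: a nuclear
counterstain (dapi), back-scattered confocal reflectance, and transmitted
light.  Cell-type-specific reference fluorescence (green = fibroblasts,
red = tumor cells) is used once, at training time, to assign ground-truth
labels; the trained 3D CNN then classifies cells from the label-free
channels alone, and classified cells are repainted at their original
coordinates ("recapitulation").

Stages: tile → segment (marker-controlled watershed) → assign ground truth
(F index + overlap criteria) → build dataset (standardize, hold out,
balance, augment, split) → train (bootstrapped 3D CNN) → predict →
recapitulate → evaluate.

## Geometry and conventions

Voxels are anisotropic: default `(dz, dy, dx) = (4, 0.8, 0.8)` µm
(1.25 px/µm in-plane, 4 µm z-step, ~96 µm stacks → 24 planes).  All
physical parameters (blur sigmas, seed separation) are given in µm and
converted per axis.  Coordinates are 0-based `(z, y, x)`; bounding boxes
are inclusive.  Multipage TIFFs are ordered z-major, channel-minor, with a
JSON description tag carrying channel names and voxel size.

## Segmentation

The composite of the normalized dapi and reflectance channels is Gaussian
blurred (default sigma 2 µm per axis); its morphological gradient
(dilation − erosion, 6-connected) is the flooding surface.  Seeds are local
maxima of the smoothed dapi channel with a physical minimum separation
(default 8 µm, ellipsoidal footprint) above a relative intensity floor
(default 0.2 of the smoothed range).  The cell-vs-matrix mask comes from
Li's cross-entropy threshold on the blurred composite — chosen because it
keeps dim cell rims (≥99% of true body voxels on noise-free synthetic
data), where Otsu keeps only bright cores — or, alternatively, from a
trainable per-voxel random-forest classifier over a fixed multiscale
feature bank (Gaussians at 1.6/3.2 µm, gradient magnitude, Laplacian,
local variance), trained from sparse scribbles.

The watershed itself is a deterministic priority flood: a queue keyed by
(altitude, insertion order), seeds queued in increasing label order, fixed
neighbor order, 26-connectivity by default.  Ties at equal altitude
therefore resolve to the earliest-queued claim (lowest label first).  The
test suite checks voxel-for-voxel equality against an independent
linear-scan re-implementation on 100 random volumes with integer altitudes
(ties everywhere), plus symmetry and mask-monotonicity properties.

Post-filters remove regions touching the lateral tile borders or the
top/bottom z-planes (interface reflections concentrate there), regions
smaller than 15 or larger than 60,000 voxels (both bounds kept inclusive),
and regions whose integrated dapi signal does not exceed the background
estimate (median dapi over non-cell voxels × region volume).  Cells found
in several overlapping tiles are kept once, from the tile where their
centroid is farthest from a tile border.

## Ground truth

Reference masks: Huang's fuzzy-entropy threshold (implemented here,
verified against a brute-force objective scan) for green, Li's threshold
(scikit-image) for red, both over the full 3D tile.  Reference cells are
segmented by the same watershed, flooding the gradient of each reference
channel inside its own mask, reusing the dapi seeds.  Each label-free ROI
gets: `F` and `C`, its voxel counts inside the green and red masks; the
F index `F/(F+C)` (> 0.5 → fibroblast, ≤ 0.5 → tumor, the boundary going
to tumor); `stain_overlap_frac = max(F, C)/|ROI|`; and
`best_gt_overlap_frac`, its best overlap fraction with any single
reference cell.  A label is accepted only if stain overlap ≥ 0.5 (inclusive)
AND best reference overlap > 0.9 (strict) AND the F-index class matches the
best reference cell's class; otherwise the ROI is ambiguous and excluded
from training.  Overlap denominators are the ROI's own voxel count, since
segmented cells are systematically slightly smaller than the stained cells.

## Dataset

Standard tensor: 3 channels (dapi, reflectance, transmission) ×
20×50×50 voxels.  The ROI bounding box is cropped, out-of-ROI voxels are
zeroed (the tensor encodes the segmented cell, not its neighbors), and the
crop is zero-padded at high indices (a `pad_center` option exists); cells
exceeding the standard size in any dimension are rejected.  Whole source
images are held out as a strict test set before augmentation.  Classes are
balanced by down-sampling the majority, dropping the lowest-confidence
cells first (confidence = |F index − 0.5|, seeded random tie-break).
Augmentation copies every cell at 90°/180°/270° in-plane rotations.

Splits default to 70/15/15 and are drawn over cells, with all rotations of
a cell kept in one split.  Splitting after augmentation without grouping
would let rotated twins of one cell appear in both train and test; grouping
is the default here, and `group_rotations=False` restores the
augment-then-split behavior for comparison.

## Classifier

A compact VGG-style 3D CNN: three blocks of
[conv3d (16 filters, kernel 5, same padding) → batch norm → ReLU →
max-pool (2,2,2)], then flatten → dense(128, ReLU) → 2-way softmax.  With
pooling (2,2,2) on a z-depth of 20, three blocks are the practical depth
limit ((20,50,50) → (2,6,6)); deeper stacks collapse the z-axis and are
rejected at configuration time.  Loss is categorical cross-entropy
(standard negative log-likelihood; predicted probabilities clipped at 1e-7).
Optimizer: Adam, initial learning rate 1e-4 with exponential decay
(default ×0.96 per epoch), batch size 16, up to 30 epochs.

Training uses a bootstrap protocol: `n_runs` (default 25) independent runs,
each re-randomizing the train/val/test partition, weight initialization and
batch order from a run seed derived from the master seed; within a run the
checkpoint at minimum validation loss is kept; across runs the model with
the lowest best validation loss is selected.  Per-channel standardization
(zero mean, unit variance) is fitted on each run's training split and
stored with the model; it is required for stable optimization across
channels with very different dynamic ranges.

The layers are implemented directly on numpy, with convolutions evaluated
in the frequency domain (scipy.fft): forward, input-gradient and
weight-gradient all reduce to pointwise spectral products, which on one CPU
core is severalfold faster than im2col+GEMM at this kernel size.  Large
spectral batches are processed sample-by-sample to stay cache-resident.
Max-pool backward routes gradient to every voxel attaining the block
maximum (ties share), keeping backprop deterministic.  All forward passes
in inference mode use the running batch-norm statistics and are
reproducible bit-for-bit for a fixed model.

## Synthetic spheroids

The generator emulates the study conditions so every stage is testable
without external data: ~1:1 fibroblast/tumor rosters (largest-remainder
rounding), cell centers rejection-sampled inside an ellipsoid with a
minimum physical separation (default 18 µm — "well-separated" in the sense
of the counting experiments), anisotropic Gaussian nuclei on the dapi
channel, cytoplasmic reflectance bodies with low-amplitude matrix speckle
and optional bright interface planes at the top/bottom of the stack,
transmission as a bright background minus cell-shaped attenuation, and
class-exclusive reference stains that fill each cell to a small halo
(2.5 µm) beyond the reflectance-bright cytoskeleton — so segmented ROIs sit
inside their stained cell, as in the real data.

The class signal lives in the reflectance texture: band-limited noise whose
correlation length (fibroblasts smoother/elongated, tumor granular) and
amplitude (tumor higher-contrast) both interpolate with `texture_effect`.
At `texture_effect = 0` the two classes are identical in distribution (a
rank test on per-cell texture statistics confirms this); at 1.0 the
contrast gap (amplitude factors 0.2 vs 1.8 of the base texture amplitude)
makes per-cell reflectance variance a strongly separating feature.  The
gap at 1.0 is deliberately wide: the test-scale corpora afford only
hundreds of gradient steps, orders of magnitude fewer than a full-scale
training, so "full separation" is defined as a signal learnable at that
budget.  Transmission carries a weak attenuation difference
(`transmission_effect`, default 0.3 × texture_effect; set to 0 to make
reflectance the only informative channel, as the channel-ablation fixture
requires).  The generator does not model optics (PSF, refraction),
migration, or fibrin microstructure; passing tests demonstrate pipeline
correctness and signal recovery under these idealized conditions, not
classifier performance on real microscopy.

## Problem sizes in the test and acceptance suites

Experiments are scaled to desk hardware: the classifier signal-recovery
fixture uses 408 oracle-labeled cells from 8 synthetic images (1 held out
strictly), 3 bootstrap runs × 10 epochs with a 60/20/20 split (the larger
validation share stabilizes best-epoch selection at this corpus size);
monotonicity and ablation checks use 120-cell corpora with single runs of
5–6 epochs; the rotation-invariance check trains one augmented run
(96 cells × 4 rotations, centered padding so content position is
rotation-symmetric, 8 epochs); the end-to-end demo
uses 3 images × 12 cells, 2 runs × 5 epochs, and is executed twice to
verify bit-identical metrics.  The watershed oracle sweep uses 100 random
volumes up to 20³ voxels.  Counting agreement is evaluated on
single-spheroid images against the generator roster, with ROI-to-roster
matching by majority overlap among body-hitting voxels (an ROI touching no
body at all counts as a false positive).

## Known limitations

- The reflectance texture model is a stand-in: no quantitative description
  of real intra-cellular reflectance differences informs it.
- Threshold-mode masks assume bright cells on a dark matrix; dense real
  matrices may need the pixel-classifier mode with user scribbles.
- The recapitulated volume resolves ROI overlaps by label order, which can
  clip a few voxels from later cells (counted and logged).
- Training on CPU bounds practical corpus sizes; the architecture is small
  by design and no GPU path is provided.
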