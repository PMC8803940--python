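# Methods

This document describes the scientific model implemented by `motionseg`,
all user-facing parameters with defaults and units, what the synthetic
data emulate (and what they do not), and the numerical design decisions.

## 1. Geometry and conventions

Arrays are indexed `(i, j, k)` with `i` = lateral (left–right), `j` =
superior–inferior, `k` = anterior–posterior. The anterior–posterior axis
is the long axis of the fixed crop box and is also treated as the
phase-encode direction of the simulated acquisition. NIfTI images are
reoriented to this canonical layout on read (RAS+ followed by an axis
swap placing A–P last). Voxel extents are half-open `[start, start +
length)` with 0-based indices.

Two geometries are packaged (`motionseg.geometry`):

| | conform shape | crop box | subvolume | step | grid |
|---|---|---|---|---|---|
| `FULL_SCALE` | 256^3 @ 1 mm | 152 x 152 x 184 | 76 x 76 x 92 | 38 x 38 x 46 | 3 x 3 x 3 = 27 |
| `DESK_SCALE` | 64^3 @ 1 mm | 40 x 40 x 48 | 20 x 20 x 24 | 10 x 10 x 12 | 3 x 3 x 3 = 27 |

The crop box is 15.2 cm lateral and superior–inferior and 18.4 cm
anterior–posterior at 1 mm isotropic resolution. Subvolumes are half the
cropped extent per axis and are sampled at quarter-extent steps, giving
the 27-subvolume overlapping grid; interior voxels are covered by up to 8
subvolumes. The desk geometry preserves every structural ratio
(conform : crop : subvolume : step) at integer voxel counts — 40 x 40 x 48
is the smallest box that keeps the crop divisible by 4 on every axis with
the same lateral/AP aspect ratio (0.152/0.184 scaled by 64/256 gives 38 x
38 x 46; rounding up to divisibility by 4 gives 40 x 40 x 48). It exists
so that training and the full study loop run in minutes on one CPU.

Preprocessing (`core_io.conform`): resample to 1 mm isotropic (3rd-order
spline for intensities, nearest-neighbour for labels) and center crop/pad
to the conform shape (zeros for intensities, the Unknown label for
masks). Intensities are then standardised to zero mean, unit variance
over the whole volume (`normalize_intensity`).

## 2. Stage 1: localisation network (`cropnet`)

A regression CNN maps the 2x-downsampled conformed volume (spline
downsampling, factor 0.5) to the 6-vector `[i0, j0, k0, d_i, d_j, d_k]`
(tight-box vertex and edge lengths, in downsampled voxel units). The
architecture is 16 convolutional layers (3^3 kernels, SAME padding) with
Swish activations (`x * sigmoid(x)`), spatial reduction exclusively via
stride-2 convolutions (no pooling anywhere), a flatten, two hidden dense
layers (64, 32 units, Swish), and a linear 6-unit output. Filter counts
start at 8 and double at each reduction up to 32.

Training (`CropTrainConfig`): mean squared error on the 6-vector plus an
L1L2 weight penalty (l1 = l2 = 0.01), Adam, batch size 8, early stopping
on validation MSE with patience 20 and best-weight restore, and the
exponentially decaying learning rate

    lr(epoch) = lr0 * r**(epoch / s),   r = 0.92, s = 10.

`lr0` defaults to 1e-3: the printed schedule constant "10e-4" is read
literally (10 x 10^-4); pass `lr0=1e-4` for the alternative reading.

Only the predicted box **center** is used downstream (`finalize_bbox`):
the fixed-size crop box is placed around it (center rescaled by
1/downsample_factor) and clipped by *shifting* — never shrinking — so the
output shape is input-independent. During training of stage 2, where the
ground-truth mask is available, the box is centered on the mask-derived
tight box instead.

## 3. Stage 2: segmentation network (`segnet`)

An encoder–decoder ("U-Net-style") CNN scores each subvolume: two
stride-2 reductions, a bottom block, and two nearest-neighbour x2
upsampling stages whose outputs are **concatenated** with the
corresponding encoder activations (two skip connections). Every hidden
convolution is followed by batch normalisation and ReLU; the output is a
1^3 convolution to `n_classes` logits. Only convolutional layers are
used (no pooling). Base channel count defaults to 8 (doubling to 16/32
at the reductions).

Loss: softmax probabilities enter the 1:1 weighted sum of

- **Focal loss**, mean over voxels of `-alpha * (1 - p_t)**gamma *
  log(p_t)` with alpha = 4, gamma = 2;
- **Generalised Dice Loss**, `1 - 2 * sum_l w_l |P_l ∩ Y_l| / sum_l w_l
  (|P_l| + |Y_l|)` with `w_l = 1 / (n_l + eps)^2`, `n_l` the
  ground-truth voxel count of class l and eps = 1.0 (keeps weights finite
  for absent classes; eps is configurable).

The analytic gradient (including the softmax chain `dz = p * (g - sum_c
p_c g_c)`) is finite-difference-verified in the test suite.

Training (`SegTrainConfig`): RMSprop (lr 1e-3, an implementation choice),
batch size 2, early stopping with patience 25 and best-weight restore,
and per-epoch online augmentation: with probability 0.3 the cropped pair
is rigidly rotated (per-axis angles uniform in [-1, 1] degrees) about a
center offset by integers in [-2, 2] voxels; intensities are trilinear,
labels nearest-neighbour.

Inference (`segnet.predict`): conform -> normalize -> predicted fixed box
-> score all 27 subvolumes (eval-mode batch norm) -> sum scores into a
full-extent accumulator, divide by per-voxel coverage, argmax (ties to
the lowest class id) -> embed into the full frame padded with Unknown.
Merging the one-hot scores of the ground truth reconstructs the mask
exactly (round-trip acceptance test).

## 4. Phantoms and the motion model (`phantom`)

Each "subject" is a layered ellipsoidal head: scalp, skull, CSF shell, a
cortical shell split into four quadrant parcels, a white-matter core,
two ventricles, and up to 8 deep-gray nuclei at stereotyped offsets.
Default tissue means (arbitrary T1-like units): scalp 70, skull 25, CSF
45, cortex 85, white matter 115, ventricle 40, nuclei 130 + 12n;
additive Gaussian noise sd 4. The anatomy seed fixes the geometry; the
noise seed is redrawn per acquisition so the same head can be "scanned"
repeatedly (test–retest emulation).

Motion is simulated in k-space: the corrupted fraction of phase-encode
planes (axis `k`, DC plane always preserved) is split into `n_nods`
contiguous blocks at random positions; each block's k-space is replaced
by that of the rigidly displaced object — translations as exact linear
phase ramps (energy-preserving by Parseval; verified to ~1e-7 relative),
rotations by resampling the rotated image (trilinear; loses ~1–2% energy
at the block edges). The magnitude image is returned. Ground-truth masks
are never touched by the motion simulation.

Severity and tiers: `severity = corrupted_fraction *
(max_translation_mm + max_rotation_deg)`; thresholds HM1 <= 0.35 < HM2 <=
1.5 < HM3, ties to the better tier. The packaged study design draws, per
subject, one motion-free rest acquisition (CONV, tier HM1), one
mild-motion acquisition (MOVE1: 5 nods, magnitudes U(0.2, 2.2),
fraction U(0.05, 0.35)) and one strong-motion acquisition (MOVE2: 10
nods, magnitudes U(1.0, 4.0), fraction U(0.20, 0.55)), plus optional
motion-free retests.

What the phantom does **not** emulate: real cortical folding and
anatomical variability, B0/B1 field inhomogeneity, partial-volume
effects, through-plane or continuous (non-segmented) motion, spin
physics, or scanner-specific reconstruction. Results on phantoms
characterise the pipeline's mechanics, not clinical performance.

## 5. Reliability evaluation (`evalrel`)

Per region (region binarized, Unknown never a region):

- **DSC** `2|A∩B| / (|A|+|B|)`; NaN when both masks are empty.
- **IoU** `|A∩B| / |A∪B|` (= DSC/(2−DSC)); NaN when both empty.
- **HD** symmetric Hausdorff distance between boundary voxels (6-
  connectivity erosion residue) in mm, optional percentile variant
  (e.g. 95); NaN when either mask is empty.
- **VD** `|V_g − V_p| / V_g` with the reference as ground truth; NaN when
  `V_g = 0`.

NaN values are excluded from averages and counted per aggregation cell
(`n_excluded_<metric>`); aggregation cells are (subject, method,
macro-region, pairing type), with macro-regions cortical / subcortical /
other from the label scheme.

Pairing designs: `head_motion` pairs each subject's motion-free rest mask
(only when its tier is HM1; other subjects are excluded and reported)
with every motion acquisition (pairing type `HM1-<tier>`); `test_retest`
pairs every within-subject combination, the earlier acquisition serving
as reference.

Method comparison: exact two-sided Wilcoxon signed-rank on per-subject
values when both methods cover identical subject sets, Mann–Whitney U
otherwise; all-zero paired differences are flagged degenerate rather
than tested; at least 3 observations per method required.
Benjamini–Hochberg correction is applied within each metric's family of
comparisons; significance at adjusted p < 0.05.

The comparison method packaged as `"atlas"` (`motionseg.baseline`) is a
deliberately simple probabilistic-atlas segmenter (voxelwise label
frequencies + per-class Gaussian intensity model, maximum posterior),
authored by this package as a synthetic stand-in for a classical
atlas-driven pipeline — not a re-implementation of any external tool.

## 6. Numerical design decisions

- **NumPy NN engine.** All layers (3D convolution via im2col/GEMM,
  dense, batch norm, nearest-neighbour upsampling, Swish/ReLU) and both
  optimizers (Adam, RMSprop) are implemented directly on NumPy with
  explicit backward passes, each verified against central finite
  differences in float64. Networks default to float32 compute (roughly
  halves time and memory); layers accept `dtype=` for full precision.
- **Strided convolutions only.** Constructing either network with
  pooling raises; the layer census is asserted in the tests.
- **Determinism.** One run seed feeds `numpy.random.SeedSequence`, which
  spawns independent child seeds (reduced mod 2^31) for phantoms, both
  trainings, and the study; repeated runs are byte-identical.
- **Demo defaults** (`pipeline.DemoConfig`): 20 training + 3 validation +
  4 held-out phantoms, 40 crop epochs, 7 segmentation epochs (the
  early-stopping patience never triggers at these budgets; the best
  validation-loss weights are restored), 12 study subjects at desk
  geometry — chosen from held-out learning curves so the complete
  demonstration (training included) finishes in under 15 minutes on one
  CPU while reaching held-out localisation error under 10% of the
  crop-box diagonal and held-out mean foreground Dice >= 0.8.
- **Edge policies.** Argmax ties break to the lowest class id; severity
  ties at a tier threshold take the better tier; empty-region metrics are
  NaN (excluded and counted), not zero.
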