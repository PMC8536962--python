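# Methods

## Model

The segmentation network is a deep encoder–decoder with side-output
supervision. Contracting levels ℓ = 1…8 each apply two size-preserving
3×3 convolutions with ELU followed by batch normalisation, with 2×2
max pooling (stride 2) between levels; feature channels are
32, 32, 64, 64, 128, 128, 256, 512, scaled uniformly by a width
multiplier. Expansive levels mirror the contracting ones: a stride-2
kernel-2 transposed convolution halves the channel count and doubles
resolution, the matching contracting feature map is concatenated, and
the same two-convolution block follows. Dropout (rate 0.5) sits on
the last three contracting and first three expansive levels, where the
representation is densest.

Every block is tapped as a side output: s₁…s₈ after each contracting
block (before pooling), s₉…s₁₅ after each expansive block, deepest
first. A tap at depth k is reduced by a 1×1 convolution with ELU to
`side_head_channels` (default 1) channels and upsampled to input
resolution by k stacked stride-2 transposed convolutions — stacked
stages rather than one large-stride kernel, to limit checkerboard
artefacts. Four heads concatenate tap subsets channel-wise (all taps;
all but s₁₅; the contracting taps s₁…s₈; the expansive taps s₉…s₁₅),
apply two 3×3 convolutions (ELU, `post_concat_channels` filters) and a
1×1 convolution with a sigmoid; the fifth map P_f is a 1×1 sigmoid
convolution of the final expansive feature map. A single sigmoid
channel is emitted rather than a 2-class softmax — the two are
equivalent for binary segmentation and the threshold is applied
downstream (default 0.5, with ≥ tie-breaking).

Two constructors share this pattern: `build_simou_spec` (the deep
8-level network, depth configurable) and `build_simo_unet_spec` (a
plain 5-level U-Net with channels 64…1024 wrapped with the analogous 9
taps and 5 heads). Size-preserving ("same") padding is used
throughout: with unpadded convolutions the 15 full-resolution tap maps
and equal-size skip concatenations would require ad-hoc cropping at
every join. `post_concat_channels` defaults to 64 at width 1 and is
scaled by the width multiplier like every other channel count, so thin
models are thin everywhere — at full width the heads operate on
64-component feature vectors.

Weights are initialised from a zero-mean Gaussian with standard
deviation √(2/η), η = k_h·k_w·c_in incoming nodes per neuron
(He-style, matching the alternating convolution/ELU structure); biases
start at zero, batch-norm gain at one. All randomness is a pure
function of the seed.

## Loss and training

For one image with flattened binary truth y and predicted
probabilities p, the hybrid loss is

    L = −[ mean_r(½·y_r·ln p_r) + (2·Σ y p + ε)/(Σ y + Σ p + ε) ],

averaged over the batch. The cross-entropy term weights foreground
only (the brain occupies a small part of the field of view; the soft
Dice term supplies the background pressure), and the loss is bounded
below by −1, attained exactly at p = y. Numerical choices: the
probability is clipped to [10⁻⁷, 1−10⁻⁷] inside the logarithm only, so
the Dice term keeps exact zero sums and an empty prediction of an
empty truth scores ε/ε = 1 (loss −1); Dice smoothing ε = 10⁻⁶. The
training objective sums this loss over the five heads with weights αₜ
(default all 1 — no head is privileged).

Optimisation uses RMSprop with learning rate 3·10⁻⁴, moving-average
decay ρ = 0.8 and batch size 32 (defaults of `TrainingConfig`);
⌈n/batch⌉ steps per epoch; early stopping monitors the validation loss
with patience 100 within a 1000-epoch budget and the best-validation
weights are restored. Per-epoch validation Dice/Jaccard of the
mean-fused prediction are recorded alongside both losses. When
augmentation is on, each epoch sees every original slice plus one
freshly augmented copy: a rotation uniform in ±180°, a zoom factor
uniform in [0.1, 2.0] (taken literally, extreme as zoom 0.1 is), and
independent horizontal/vertical flips — linear interpolation for
images, nearest-neighbour with 0.5 re-binarisation for masks,
zero-filled out of bounds, output cropped/padded back to shape.

## Evaluation protocol

Folds are planned over whole subjects — all slices of a foetus stay in
one fold — stratified by quartile of mid-slice brain area (a
gestational-age surrogate in phantoms; any manifest column can be
substituted), with subjects dealt round-robin so within-stratum fold
counts differ by at most one. Jaccard, Dice and sensitivity are
computed per 2D slice from confusion counts and averaged over the
slices of a case whose ground truth contains foreground; slices with
empty truth are excluded from those averages (undefined denominators)
but count fully toward volumes. The Hausdorff distance is the exact
symmetric maximum (not a percentile), per slice in mm with pixel
coordinates scaled by (dx, dy), undefined (flagged, never zero) when a
mask is empty; 2D-per-slice rather than 3D is used throughout, since
the segmentation itself is 2D. Brain volume is the foreground voxel
count × dx·dy·dz / 1000 (cm³); MAVD is |V_auto − V_manual|. Volume
agreement reports squared Pearson correlation and Bland–Altman
statistics (mean difference ± 1.96 sample sd of auto − manual).

## Phantom generator

Each synthetic subject is a stack of 12–18 slices of 64×64 px at
1.5 mm in-plane and 2.3 mm slice thickness (mid-range of the 2.0–2.6 mm
typical of foetal acquisitions). The brain is a randomly placed,
oriented and sized ellipse (semi-axes 8–18 px, i.e. 12–27 mm) whose
per-slice scale follows floor + (1−floor)·(4t(1−t))^q over normalised
slice position t, so area peaks mid-stack and shrinks to ~9 % of the
peak at the ends; a bright skull ring surrounds it at `skull_gap_px`
(which may be ≤ 0 to force brain–skull overlap), with head tissue
between. Brain/tissue contrast is scaled toward the ends by
`contrast_falloff` (default 0.35), Gaussian noise (sd 0.04) is added,
and with probability 0.15 a slice receives a faint (15 %) shifted
replica of itself, mimicking motion ghosting. These defaults target
the regimes that make the clinical task hard — tiny low-contrast end
slices, skull-adjacent boundaries, ghosting — and the artefact rates
are free parameters chosen once at plausible values, as no
quantitative artefact statistics exist to emulate.

What the phantom does **not** model: MR physics (no k-space
simulation, no bias field beyond the contrast falloff), anatomical
texture (gyri, ventricles, tissue interfaces), non-elliptical brain
shapes, and inter-slice motion of the anatomy itself. Passing tests
on phantoms therefore demonstrate that the pipeline — architecture,
loss, optimisation, fusion, metrics, volumetry — is correct and that
the ensemble behaviour emerges, not that clinical-grade accuracy would
be reached on real foetal MRI.

## Scaled-down experiment sizes

The end-to-end experiment used by the tests and the acceptance script
runs on one CPU: 12 subjects at 64×64, a width-1/8 model of 7 levels,
15 epochs of RMSprop on the ~10 training subjects (two of which form
the early-stopping validation split), batch size 8. Seven levels is
the deepest architecture a 64×64 input admits (spatial size must be
divisible by 2^(levels−1); the bottleneck is then 1×1), and the batch
size is scaled down with the cohort — at batch 32 an epoch over ~120
slices would make only four gradient updates. Under these conditions
the mean-fused held-out Dice reaches ≈ 0.85–0.96 across seeds and
exceeds the down-path-only head P_d, reproducing qualitatively the
ensemble's advantage over any encoder-only prediction; the
under-trained P_f and the outlier-sensitive P_MAX trail, as expected
for a deep path given few updates and for a maximum statistic. The
volume-agreement statistics in the acceptance script pool training and
held-out subjects (n = 12): two held-out cases cannot support a
correlation, and at this scale the statistic demonstrates the
volumetry pipeline rather than generalisation.

## Other design notes

- The in-memory case container is `VolumeStack` (slice, row, column);
  NIfTI I/O (canonical, via nibabel) stores (row, column, slice) with
  the spacing on the affine diagonal; PNG+JSON per-slice I/O is
  provided for inspection and fixtures, 16-bit quantised with the
  scale recorded in the sidecar. Masks are 8-bit {0,1}; probabilities
  32-bit float.
- Ties in 2×2 max pooling share the gradient equally; batch-norm
  running statistics use momentum 0.9; RMSprop ε = 10⁻⁷.
- Per-head map ordering everywhere is (d,ux; d,u; u; d; f).
- Degenerate inputs fail loudly: undefined metrics return missing
  values with a log notice, empty-truth cases are excluded and logged,
  geometry and configuration errors name the offending field.

## Known limitations

- Training is single-threaded CPU numpy; full-width, full-resolution
  training at the clinical scale is out of reach (the design trades
  speed for zero framework dependencies and exact testability).
- The Hausdorff distance is the exact maximum, which is
  noise-sensitive; a percentile variant is not implemented.
- No DICOM support and no learned fusion weights (fusion is mean /
  median / max by definition).
- Inter-method significance testing (Friedman/Nemenyi) is out of
  scope; standard statistics packages cover it.
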