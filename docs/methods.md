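# Methods

`contrastshift` studies a specific, clinically important failure mode of
learned CT organ segmentation: a model trained on contrast-enhanced CT
(where iodine raises the attenuation of perfused organs, most strongly
the kidney) can fail almost completely on non-contrast CT of the same
anatomy, and augmenting training with GAN-translated synthetic
non-contrast images largely rescues it. The package reproduces the whole
mechanism at desk scale — synthetic phantoms, curation, unpaired slice
translation, 3D segmentation, cross-validated evaluation and paired
statistics — on a single CPU.

## Phantom model

A phantom is a 3D grid (default 48³ for general use, 32³ in the
experiments; 1 mm isotropic spacing) of soft tissue at 40 HU containing:

* a **kidney-like organ**: an ellipsoid at base 80 HU that gains
  +150 HU under contrast plus a multiplicative low-frequency texture
  (amplitude 40 HU, correlation length 3 voxels) — the texture is a
  contrast-only cue, emulating the characteristic enhancement pattern of
  renal parenchyma;
* an **aorta-like tube**: a thin z-elongated ellipsoid at 40 HU gaining
  +260 HU, reaching the 300 HU clip ceiling under contrast;
* a **fat slab** at −100 HU (15% of the grid along x), providing the
  region of interest for fat-noise estimation;
* additive Gaussian acquisition noise (default SD 10 HU), drawn
  independently per domain.

The two domains of a case share identical anatomy and masks, so paired
ground truth exists for evaluation even though translator training only
ever sees unpaired volumes. Organs are analytic ellipsoids, so mask
volumes have exact oracles. Population variability comes from uniform
jitter of organ centers (±5% of the grid), semi-axes (±2%), base HU
(±5 HU) and enhancement (±15 HU).

The kidney's +40 HU baseline contrast over soft tissue is deliberate: it
makes the organ segmentable *without* contrast, so the out-of-
distribution failure of a contrast-trained model is a learned-shortcut
failure (the model keys on enhancement and texture), not an
impossibility of the task — the same interpretation the grass-detector
analogy suggests for real kidneys.

What the generator does **not** model: anatomical realism, partial
volume effects, scanner physics (beam hardening, dose-dependent noise
correlation), pathology, multiple contrast phases. Passing tests
therefore demonstrate the *mechanism* of the distribution shift and its
rescue, not clinical performance numbers.

## Preprocessing and curation

Volumes are clipped to [−200, 300] HU (the iodine-sensitive window) and
z-scored over the full grid. Acquisition noise is estimated as the
sample SD of voxels in the conventional CT fat window [−150, −50] HU
(≥100 voxels required). Translator pools are gated by a contrast
classifier: probability > 0.8 → contrast pool, < 0.2 *and* fat-noise
SD < 15 HU → non-contrast pool; everything else rejected (strict
inequalities). At desk scale the classifier is a logistic model on a
16-bin HU histogram — only its thresholded probabilities are consumed,
so the gating contract is identical to a deep classifier's.

## Slice translator (CycleGAN)

Two generators translate 32×32 axial slices between domains; two patch
discriminators (scores over 8×8 receptive-field patches) drive a
least-squares adversarial objective. Generators are residual
encoder-decoders (7×7 entry conv, two stride-2 downsamples, 3 residual
blocks at width 32, two learned upsamples, 7×7 output conv) with
instance normalization, wrapped in a **global residual connection**:

    G(x) = x + delta_max * tanh(body(x)),    delta_max = 3

in normalized intensity units (`identity_init=True` zero-initializes
the final body convolution, making an untrained generator *exactly* the
identity — a deterministic oracle for `translate_volume`).

Training is two-phase. For the first 50 iterations the generators are
pretrained toward identity with the cycle and identity penalties only
(discriminators train normally throughout); the generator optimizer is
then reset and the full adversarial objective takes over. The rationale
is a desk-scale failure mode we measured: a conventionally initialized
generator spends hundreds of iterations unlearning its random output and
inflates Adam's second-moment estimates along the way, after which the
adversarial gradient can no longer move it — translation never develops
within a 500-iteration budget. Starting the adversarial phase from a
near-identity generator with fresh optimizer state lets the adversarial
signal shape the translation from its first iteration, while the warmup
phase preserves a meaningful (large, decaying) cycle-loss trajectory.

Cycle-consistency and identity penalties are optimized as **squared
error**. The canonical mean-absolute-error cycle metric has a
constant-magnitude (sign) gradient that does not shrink as the
reconstruction approaches identity; near identity it swamps the
comparatively weak adversarial gradient (~8:1 on the final generator
convolution at the reference weights) and freezes training within the
desk-scale budget. The squared surrogate's gradient vanishes at
identity, restoring the intended balance. The training history records
the canonical MAE cycle loss alongside the optimized surrogate.

Loss weights are λ_cycle = 2, λ_identity = 1 at desk scale. The
full-scale convention (λ_cycle = 10 with half-weight identity) pins the
generator to the identity mapping within 500 iterations — measured mean
gap reduction on the constant-shift benchmark drops from ~0.6 to ~0.3 —
because the ill-posed inverse direction cannot keep up, so every
translation the forward generator attempts is taxed by the cycle term.

Optimization: Adam (β = 0.9/0.999), lr 2e-3, fixed for the first half
of training then linear decay to zero, image buffer of 50 past fakes
for discriminator updates, batch size 4.
Volumes are translated once and cached, never on the fly; translation is
slice-wise along z (mirroring the memory constraints that force 2D
translation at full scale), and `slice_consistency_sd` quantifies the
resulting slice-to-slice inconsistency.

## Segmenter

A residual 3D U-Net: stride-2 kernel-7 entry convolution (halves every
spatial dimension before any feature maps are stored), pre-activation
residual blocks (GroupNorm → leaky ReLU → 3³ conv, twice), stride-2
downsample convolutions, additive skip connections at every level
except the highest, transposed-convolution upsampling, and a stride-2
transposed convolution restoring input resolution before a 1-channel
sigmoid head. Desk defaults: 32³ input, base width 8, two levels below
the entry, GroupNorm groups 4 (16 at full scale; the group count must
divide every channel count), leaky slope 0.01, batch size 2.

Training minimizes the smoothed Dice loss

    Loss = 1 − 2(⟨X,Y⟩ + s) / (ΣX + ΣY + s)

with s = 1; evaluation uses s = 0 on the 0.5-thresholded mask. The
denominator is the sum of mask magnitudes (the standard smoothed-Dice
reading — a literal union there would make the perfect-overlap loss
nonzero at s = 0). An empty prediction against a non-empty reference
scores Dice 0 by convention, keeping out-of-distribution failures finite
and comparable. Degenerate both-empty input at s = 0 is an error; soft
predictions never produce it during training. Early stopping: training
runs to `max_iterations` (batch-iterations) or until validation Dice
fails to improve for `patience_epochs` epochs, where an epoch is one
pass over the cached augmented variants; the best-validation checkpoint
is restored.

## Augmentation

All regimes share a spatial stack applied with identical parameters to
image (trilinear) and mask (nearest neighbor): per-axis flips (p = 0.5)
→ per-axis rotations uniform in ±30° → elastic deformation from a
b-spline control lattice (10 points per axis, i.i.d. Gaussian
displacements, SD 8 voxels at full scale, scaled by grid ratio to ~1.3
voxels at 32³) → random crop (full-size by default). Out-of-grid voxels
are filled with the image minimum (the clip floor). The `histeq` regime
prepends a fair coin between the original and a 64-bin flat-target
histogram equalization (monotone CDF remapping, applied before
z-scoring); the `cyclegan` regime prepends a fair coin between the
original and the precomputed translated volume. 16 variants per volume
are cached and sampled uniformly. Random streams are keyed by
(seed, case id, variant index) with separate substreams for the
intensity coin and the spatial stack, so all regimes share identical
spatial augmentation and differ only in the intensity branch —
between-condition differences are attributable to the augmentation
method alone.

## Experimental design and statistics

In-distribution cases are split 75%/5%/20% (train/validation/test) by
largest-remainder integer allocation (n = 40 → 30/2/8; n = 66 →
50/3/13). k-fold cross-validation rotates the test block; every case is
tested exactly once. The out-of-distribution set (non-contrast phantoms
from an independently sampled population) is never used in training and
is evaluated *in full by every fold's model*; its summary SD is across
folds. Leakage is asserted on every run.

Conditions are compared per matched (case, fold) pair with the Wilcoxon
signed-rank test: zeros discarded, ties mid-ranked, two-sided p — exact
enumeration for n ≤ 25 pairs, normal approximation with continuity
correction beyond. The implementation is cross-checked in the test
suite against an in-repo exhaustive sign-enumeration oracle.

## Desk-scale experiment sizes

The end-to-end experiment uses 32³ phantoms, 40 in-distribution cases
(→ 30/2/8 per fold), 10 out-of-distribution cases, 2 folds, the
`standard` and `cyclegan` conditions, 500 translator iterations, and
up to 480 segmenter iterations per model. These sizes preserve the
qualitative pattern of the full-scale design (near-total OOD failure
of the contrast-trained kidney model; large rescue by domain-swap
augmentation; in-distribution parity) while remaining CPU-trainable;
the absolute Dice values are not comparable to full-scale results.

## Numerical and engineering choices

* All networks run on a small tape-based numpy autodiff engine written
  for this package (`contrastshift.nn`); convolution forward/backward
  passes are im2col/col2im with BLAS matmuls and are validated against
  finite differences in the test suite.
* Weight init is fan-in-scaled normal from explicit generators; every
  model, phantom and augmentation stream is reproducible from integer
  seeds (bit-exact reruns in single-threaded mode).
* Binarization threshold 0.5 on the sigmoid output; rotation Euler
  order x→y→z; voxel indices 0-based with z the slice axis.
* B-spline displacement fields are cubic-spline upsampled from the
  control lattice; masks are warped with nearest-neighbor so they stay
  strictly binary.

## Known limitations

* The translator learns an intensity remapping on near-pointwise cues;
  it is not evidence that anatomically complex enhancement patterns
  translate correctly (stents and atypical kidneys fail even at full
  scale).
* Gaussian additive noise is a modeling choice; real low-dose CT noise
  is correlated and dose-dependent.
* The 2-fold, 40-case experiment gives coarse fold-level SDs; the
  Wilcoxon comparison operates on per-case pairs and is better powered.
* Single-organ (binary) segmentation only; one model per organ.
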