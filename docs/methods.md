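# Methods

This note records the modelling and numerical choices behind `papcell` in
enough detail to re-derive every number the test suite checks.

## Synthetic phantoms

`phantoms.generate_dataset` draws stained elliptical cells on a textured
background: a cytoplasm ellipse with a darker nucleus ellipse inside it, with
per-image jitter in position, orientation, axis lengths, stain colour and
additive noise.  The ground-truth mask is the exact rasterized cytoplasm
ellipse, so segmentation labels are pixel-perfect by construction.  Class is
encoded morphologically: abnormal cells have a larger nucleus-to-cytoplasm
area ratio (the cue used in cytological grading), plus a stain shift.  The
two classes overlap in every single pixel statistic; separating them requires
shape-aware features, which is what makes the classification tasks
non-trivial at small image sizes.

Phantoms are a *mechanistic testbed*, not a realism claim: they validate the
plumbing (architectures, training loops, augmentation placement, leakage
hygiene, metrics) with checkable ground truth.  Conclusions about clinical
performance do not transfer from phantoms.

## Segmentation models and parameter accounting

Both U-Net variants share a 5-level encoder–decoder: base 32 filters doubling
to 512 at the bottleneck, two 3×3 biased convolutions per block each followed
by a normalization layer and ReLU, parameter-free 2× upsampling (not
transposed convolutions) with skip concatenation in the decoder, and a 1×1
sigmoid output head.

- **Standard variant**: batch normalization, dilation 1.
  Total 31,466,753 parameters, of which 12,032 are the non-trainable moving
  mean/variance pairs of the 6,016 normalized channels.
- **Improved variant**: group normalization (32 groups) and dilation-2
  encoder convolutions.  Total 31,454,721, all trainable.

`unet.reconcile_architecture` searches a grid of candidates (base filters,
depth, decoder style, conv bias) and shows that this configuration is the
unique exact match to the published parameter counts.  Two invariances follow
structurally and are tested: swapping batch→group normalization changes only
the non-trainable count (group norm keeps the same per-channel affine pairs
but no moving statistics), and changing the encoder dilation changes no count
at all (dilation affects the receptive field, not the kernel shape).

Training minimizes the Jaccard distance (smooth constant 100) with Adam.
Masks are evaluated with accuracy, precision, recall, Dice and IoU; the
closed-form identity `dice = 2·iou / (1 + iou)` is verified against
per-element loop oracles on random masks.  Convention for empty
denominators: recall is vacuously 1.0 when there are no positives to recall
(tp + fn = 0); precision is 0.0 when nothing is predicted positive.

## Numerical stack

All networks run on a hand-rolled numpy stack (`papcell.nn`): NHWC float32,
im2col GEMM convolutions, batch norm (default momentum 0.99, moving
mean/variance), group norm, spatial dropout, Adam.  Every layer's analytic
gradient is finite-difference checked.  Two testing subtleties worth
recording:

- Per-element finite differences on normalization layers sit below float32
  rounding noise; the checks use float64 inputs and a float64 random
  projection as the scalar loss.
- Whole-model gradients are checked as a *directional derivative* with
  float64-promoted parameters and step 1e-6.  At step 1e-4 the ReLU/MaxPool
  kinks inside the perturbation interval create apparent ~5% errors that
  vanish at 1e-6 — a kink artefact, not a gradient bug.

## GAN augmentor

The generator maps a latent vector to a small spatial seed and up-samples
through stride-2 transposed convolutions (filters decreasing 512→64 at full
scale), each stage followed by an identity-skip residual block, ending in a
3-channel tanh head rescaled to [0, 1] at 96×96.  The discriminator is a
plain 5-conv strided CNN with filters 32→512.  Training is the alternating
non-saturating game: Adam(4e-4, β1 = 0.5), batch 32, one-sided label
smoothing (real target 0.9).

Sample quality is tracked with the Fréchet distance under a fixed, seeded
random-projection embedding, so FID values are deterministic and cheap.
Closed-form checks: FID(X, X) = 0, and for two unit Gaussians whose means
differ by 3 the distance is 9.

Adversarial training at a few hundred steps does not converge; the
trajectory oscillates (observed FID swinging roughly 2.7–6.0 between steps
50 and 300 on a fixed instance), so the *endpoint* weights are
high-variance.  The returned generator therefore carries an exponential
moving average of the weights (decay 0.99), covering the batch-norm moving
statistics so they stay consistent with the averaged weights.  EMA is a
standard stabilization for GAN generators; it smooths the oscillation rather
than changing what is learned.

## Classification

Eight canonical backbone names (ResNet50V2, VGG19, Xception, InceptionV3,
VGG16, EfficientNetB2, MobileNetV2, DenseNet121) are registered.  Each maps
to a compact convolutional feature extractor with frozen, name-seeded random
weights whose architecture varies with the name, so ensemble members see
genuinely different feature spaces.  ImageNet-pretrained weights are an
optional enhancement this CPU-only stack does not provide; the ensemble
*mechanics* are full-scale.

- **Single classifier**: backbone → global average pooling → softmax.
- **Majority voting**: 7 members (all backbones except InceptionV3), modal
  label, ties to the lowest class index.
- **Concatenation ensemble**: all 8 backbones frozen, flattened features
  concatenated into a Dense(256) → BatchNorm → ReLU → Dropout(0.5) →
  Dense(64) → ReLU → softmax head.  Because the backbones are frozen,
  features are extracted once and only the head trains.  The head's batch
  norm uses momentum 0.9 rather than the stack default 0.99: the head trains
  for only ~tens of steps, and at momentum 0.99 the moving statistics never
  approach the batch statistics, producing a model that is accurate under
  batch statistics but useless at evaluation (observed: train loss 0.018,
  validation accuracy at chance).  With momentum 0.9 the statistics converge
  on a ~10-step timescale.

Training uses Adam + categorical cross-entropy with early stopping on
validation loss and best-weight restoration.

## Splits, augmentation placement, leakage hygiene

Real images split 64/16/20 (train/val/test), stratified by class and
deterministic in the seed: n = 419 yields 84 test images, n = 4049 yields
810.  Generated images split 80/20 into train/val and are *never* placed in
a test set; `splits.assert_no_generated_in_test` enforces this and every
pipeline calls it.

The six pipelines differ along two axes:

| pipeline          | GAN placement        | classifier input |
|-------------------|----------------------|------------------|
| Normal            | none                 | original image   |
| ROI               | none                 | ROI              |
| Nor_RES_DCGAN     | after segmentation   | original image   |
| ROI_RES_DCGAN     | after segmentation   | ROI              |
| RES_DCGAN_Nor     | before segmentation  | original image   |
| RES_DCGAN_ROI     | before segmentation  | ROI              |

"Before segmentation" means generated images (with pseudo-masks obtained by
intensity thresholding, since the GAN emits no masks) join the segmentation
training pool and flow downstream; "after" means they only augment
classifier training.  Pipelines sharing a segmentation configuration share
one trained segmenter via a cache keyed on (model config, training config,
augmentation placement, seed).

## Acceptance script

`scripts/acceptance.py --seed <int> --out <path>` recomputes the headline
quantities (exact parameter counts, metric-oracle agreement, FID closed
forms, split arithmetic, desk-scale learnability and batch-size stability,
ensemble accuracy, and the 300-step GAN smoke run) and writes them to JSON.
All stage seeds derive from the single `--seed` via a root generator.

## Limitations

- Phantoms are geometric surrogates; no claims about real cytology transfer.
- Backbones are compact random-weight stand-ins, not pretrained networks.
- The GAN smoke run demonstrates that 300 steps of training improve FID over
  an untrained baseline under a fixed embedding — a plumbing check, not a
  statement about sample fidelity.
- Everything targets a single CPU; full-scale (96×96, 31M-parameter)
  training loops exist and are exercised only at reduced scale in tests.
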