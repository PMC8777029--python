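# Methods

## The model

`segan3d` implements a semi-supervised volumetric segmentation scheme
in which one network plays two roles. An encoder-decoder segmenter (a
3D U-Net variant) emits, per voxel, a softmax over K+1 = 3 classes —
background, liver, and a synthetic *fake* class — and thereby also acts
as the discriminator of a GAN. A separate generator produces fake
image patches not from noise (which fails for 3D CT: the generator
cannot catch up with the discriminator and gradients vanish) but by
*feature restoration*: it receives the discriminator's bottleneck
features of a real unlabeled patch with a random subset of channels
zeroed, and learns to decode a realistic patch from that partial
evidence.

Training signal comes from three places:

* labeled volumes — cross entropy on the *real-class conditional*
  probabilities `p_y / (p_bg + p_liver)`;
* unlabeled volumes — `−log(1 − p_fake)`, pushing real voxels away
  from the fake class;
* generated patches — `−log p_fake` at every voxel.

The discriminator loss is the exact sum of the three. The generator
minimises feature matching: the squared L2 distance between the mean
(over space) of the discriminator's last hidden features for real and
generated patches. Updates alternate 1:1 with Adam (discriminator lr
1e-4, generator lr 3e-4, batch size 1).

## Architecture details and the open choices

The overall structure is fixed by design: four stride-2 encoder stages of
two SE modules each (the very first convolution already halves
resolution — there is no stride-1 stem), a pyramid pooling module at
the bottleneck with three parallel average-pooling branches of output
sizes 1, 2 and 5, and a decoder of three SE-module groups fed by
stride-2 transposed convolutions and skip concatenations, ending with
a transposed convolution back to input resolution, a concatenation
with the raw input patch, and a per-voxel classifier.

Where the design was genuinely open, this package chose:

* **Channel widths** — `base_channels` (default 16; 8 in the
  desk-scale experiments) doubling per level. Only the total parameter
  count of the original full-scale model is public, so widths are
  config, not fact.
* **Normalisation** — instance normalisation after every convolution.
  At batch size 1, batch-norm statistics degenerate to instance
  statistics anyway, but a running-average implementation would be
  noise-dominated; instance norm is the stable equivalent
  (`NetConfig.norm = "instance" | "none"`).
* **SE reduction** r = 4, configurable; bottleneck width is
  `max(1, C // r)`.
* **Pyramid pooling** uses adaptive average pooling (floor/ceil
  binning). This is well defined for any branch size, including
  branches larger than the bottleneck's spatial extent (bins then
  replicate voxels), which is exactly the situation with pool size 5 on
  the default 4×4×1 bottleneck of a 64×64×16 input. Branch fusion and
  final reduction are 1×1×1 convolutions; branch upsampling is
  trilinear.
* **"Splicing"** is channel-wise concatenation everywhere.
* **Transposed convolutions** use a 2×2×2 kernel with stride 2
  (non-overlapping blocks, the classic U-Net up-convolution).
* **Head** — a 1×1×1 convolution over the spliced features, i.e. a
  per-voxel linear classifier, as in the original U-Net.
* **Initialisation** — He-style normal for convolution weights, zeros
  for biases; every draw is taken from one seeded generator.
* **Feature taps** — the generator consumes the pyramid-pooled
  bottleneck (the only fixed-size, information-dense tap); feature
  matching uses the last hidden decoder features before the input
  splice.
* **Masking, not dropping** — unselected bottleneck channels are
  zeroed so the generator's input width never changes;
  `round(keep_fraction · C)` channels (≥ 1) survive, default half.

## Inference rule

At test time each voxel takes the argmax over the two *real* classes;
the fake-class mass is discarded first (ties break toward background).
This follows from the loss structure rather than taste: the labeled
cross entropy constrains only the renormalised real-class
probabilities, so the absolute fake mass on labeled data is a free
parameter that the fake-image term can inflate without penalty.
Taking a plain 3-class argmax would let that free mass overwrite
correct segmentations wherever the discriminator deems a voxel
fake-looking, even when the real-class ratio identifies the organ
correctly. The fake class is a training device, and inference treats
it as one.

## Losses: conventions

* Voxel aggregation is the mean (sum / H·W·D), making loss values
  patch-size independent; `reduction="sum"` restores raw sums.
* Logs are clamped at ε = 1e-8; `unlabeled_loss` is finite even at
  p_fake = 1 and `fake_loss` at p_fake = 0.
* The unlabeled term is implemented exactly as printed,
  `−E Σ log(1 − p_fake)`; some published semi-supervised GAN losses
  use a different real/fake decomposition, but no "correction" is
  applied here.
* Every voxel of a generated patch carries the fake target; no
  spatial weighting.
* With no unlabeled data the unlabeled term contributes 0 and the fake
  patch is generated from a labeled volume's features, so supervised +
  adversarial training still proceeds.

## The phantom generator

Phantoms emulate the data regime the method targets — a bright,
heterogeneous organ against darker tissue with blurred boundaries —
without shipping patient data. Each sample is a union of 1–3
overlapping random ellipsoids (semi-axes uniform in 0.25–0.45 of the
volume extent, random rotation), assigned +120 HU plus a smooth
heterogeneity field (three random low-frequency cosine modes, ±40 HU),
over a −60 HU background; the intensity image is Gaussian-blurred
(σ = 1.5 voxels) and Gaussian HU noise (sd 20) is added. Both classes
sit inside the [−200, +200] HU window, so windowing preserves their
contrast (≈ 115 gray levels between class means). The stored label is
the crisp pre-blur mask — blurring models partial-volume softening of
*intensities*, so a perfect segmenter scores Dice exactly 1. The organ
fraction is kept in (0.02, 0.5) by resampling.

What the phantoms do **not** model: multi-organ anatomy and
same-density neighbouring tissue, lesions, CT physics (beam hardening,
metal artifacts, anisotropic slice thickness), and inter-scanner
intensity shifts. Passing the desk-scale tests therefore shows the
pipeline's mechanics work end to end and can fit its training
distribution; it says nothing about clinical benchmark accuracy.

## Desk-scale problem sizes

All shipped experiments run on one CPU: phantoms of 64×64×16 voxels
(4 labeled + 2 unlabeled training, 2 validation, 2 test),
`base_channels=8` (≈ 0.7 M discriminator parameters), at most 2000
alternating steps with validation every 25 steps, stopping early once
the training-set Dice reaches 0.95.  The discriminator
learning rate of 1e-4 is a value suited to long schedules — the
full-scale regime trains for tens of thousands of updates — and is
retained unchanged; at a 2000-step budget the optimisation is
therefore still mid-trajectory (the labeled loss falls monotonically
and the training Dice keeps rising at the cap).  The test suite and
the acceptance script run this experiment at a 600-step budget so the
whole suite stays within a coffee break; the step budget, not the
method, is what those runs scale down. The tensor engine is float32
numpy: convolution is im2col + BLAS matmul, with input gradients
computed as dilated correlations with flipped kernels so forward and
backward share one code path; pooling and trilinear resampling are
separable per-axis linear maps whose backward is the transposed
matrices; instance normalisation is a single fused op. All randomness
flows from explicit integer seeds, so runs are bit-reproducible.

## Numerical and degenerate-input conventions

* Gray conversion truncates (`floor`) after multiplying by 255;
  `rounding="round"` is available. +200 HU maps to gray 255 exactly
  and −200 HU to 0.
* `normalize_hu` refuses values outside the window (truncate first);
  the full pipeline is monotone non-decreasing.
* Patching zero-pads each axis up to the next multiple of the patch
  shape; `stitch_patches` is its exact inverse and rejects empty or
  out-of-bounds patch sets. How trailing slices are handled is a
  package choice; padding was picked over cropping to keep
  stitch∘extract the identity.
* Dice of two empty masks is 1.0; empty vs non-empty is 0.0.
  Hausdorff and ASSD are errors on empty masks. HD is the exact
  (100th percentile) Hausdorff. Surfaces use 6-connectivity
  face-adjacency with the volume border counted as background.
* Softmax normalisation holds to 1e-6 at every voxel; the forward pass
  rejects spatial extents not divisible by 16, naming the offending
  axis.

## Known limitations

* The engine is CPU-only and single-threaded beyond BLAS; full-scale
  (256×256×16 patches, ~150 M parameters) training is out of reach by
  design. Published benchmark scores on LiTS/KiTS-class data are not
  reproduction targets here.
* With 4 labeled and 2 unlabeled volumes the discriminator memorises
  individual volumes; held-out Dice on phantoms is reported by the
  experiment but generalisation claims require realistic data volumes.
* Batch size is fixed at 1 (the study condition); the engine supports
  batching internally (the discriminator step stacks labeled,
  unlabeled and fake patches into one forward) but no multi-sample
  batch training path is exposed.
* The adversarial game is not regularised (no gradient penalty or
  spectral norm); at desk scale the feature-matching objective is
  stable, but larger runs may need such additions.
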