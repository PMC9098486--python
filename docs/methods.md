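# Methods

## Model

MEA-Net is an encoder–decoder segmentation network for binary targets
with an auxiliary edge branch.

**Encoder.** Four encoding blocks separated by 2×2 max pooling, so the
stages E1..E4 sit at full, 1/2, 1/4 and 1/8 resolution with channel
widths (64, 128, 256, 512) by default. Each block runs a main path of
a 3×3 convolution followed by asymmetric 3×1 and 1×3 convolutions and
a residual path of a 1×1 convolution; every convolution is followed by
ReLU then batch normalisation, and the two paths are summed. All
convolutions use stride 1 and "same" zero padding (3×3 → pad 1, 3×1 →
pad (1, 0), 1×3 → pad (0, 1)), so resolution changes only at the
pooling steps. Inputs must therefore have spatial sides divisible
by 8; indivisible inputs are rejected with an explicit error rather
than silently padded, keeping all intermediate shapes exact.

**Edge module.** The EFE projects each configured encoder stage
(default E1 and E2) to N = 16 channels with a 3×3 conv + ReLU + BN,
upsamples deeper stages back to E1 resolution by repeated bilinear ×2
steps, and sums the branches into a stack of 16 edge attention maps.
The MAG multiplies every attention map elementwise into the E1
features and sums the N products (because each product broadcasts one
attention map over all channels, the sum factorises as
(Σₘ Aₘ) ⊗ X₁, which is how the code evaluates it — the triple-loop
definition is kept as a test oracle). The aggregate is gated by a
squeeze-and-excitation block — global average pooling to z ∈ R^C, then
s = σ(W₁ ReLU(W₂ z)) with a bias-free bottleneck of width
max(C/16, 1) — and two 1×1 heads emit the decoder-bound edge features
Y₁ and a one-channel edge logit map Y₂ for early supervision. The gate
follows the written order (W₂ first, then W₁); both fully connected
layers are bias-free so the excitation is exactly this composition.

**Decoder.** Three cascaded decoding blocks: D3 fuses E3 with E4, D2
fuses E2 with D3, D1 fuses E1 with D2. Each block projects the
low-level input with a 1×1 conv; the high-level input is projected,
bilinearly upsampled ×2, and rescaled by per-channel sigmoid weights
computed from its global max pool through two 1×1 convolutions (ReLU
then sigmoid); the branches combine by elementwise addition (default)
or concatenation plus projection. Y₁ joins the D1 output by channel
concatenation (default) or addition, and a final 3×3 convolution plus
sigmoid produces the segmentation probability map; the edge
probability is the sigmoid of Y₂. E1 is at input resolution, so both
outputs match the input size exactly.

**Ablation switches.** `use_efe` and `use_mag` remove the respective
submodule without code changes. The two partial variants need a
convention the architecture description leaves open; this package
uses: without MAG, the two 1×1 edge heads act directly on the EFE
attention stack; without EFE, the MAG receives an attention stack from
a single 3×3 conv + ReLU + BN of E1. With both off, the network is the
plain baseline encoder–decoder and produces no edge output; with
additive Y₁ fusion, enabling the edge module changes the parameter
count by exactly its own parameters.

## Numerical core

No deep-learning framework is used: the package carries a small
tape-based reverse-mode autodiff engine (`meanet.tensor`) providing
convolution (im2col + GEMM), pooling, bilinear upsampling (as a cached
dense interpolation matrix applied separably, which makes the backward
pass an exact transpose), batch normalisation and the pointwise ops.
Compute dtype is float32; floating inputs keep their own precision, so
analytic checks can run in float64. Every backward rule is tested
against central finite differences, and forward paths against
nested-loop oracles. Weight initialisation is Kaiming-uniform from an
explicit PCG64 generator: a configuration plus seed rebuilds a
bitwise-identical network. Max pooling and global max pooling break
ties by first index, so evaluation-mode forward passes are bitwise
deterministic.

Bilinear upsampling uses the half-pixel-centre convention with clamped
borders. Batch normalisation uses eps 1e-5 and momentum 0.1 with
unbiased running variance; evaluation mode uses the running buffers.

## Losses

Soft Dice, 1 − 2Σpg / (Σp² + Σg² + ε) with ε = 1e-6, is computed per
sample and averaged over the batch (so batch size does not rescale
it); 4-d inputs are treated as batches, anything lower-dimensional as
a single sample. BCE clips probabilities to [1e-7, 1 − 1e-7] before
the logs and averages over pixels. The joint objective is
α·Dice + (1 − α)·BCE with α = 0.3; by default Dice supervises the edge
head (boundaries are a small class, where overlap losses are
well-behaved) and BCE the segmentation head. A `per_head` mode applies
the full joint loss to each head instead, and when the network runs
without its edge module the Dice term falls back to the segmentation
head so the objective stays defined.

## Metrics

Accuracy, sensitivity and Dice are per-image ratios of the pixel
confusion counts, averaged over test images; images with empty
ground-truth foreground are excluded from sensitivity/Dice with a
warning (0/0 is undefined). AUC is the pixelwise ROC area (computed
with scikit-learn), reported per image and undefined — recorded as
missing — for single-class ground truths. BF-Score extracts boundary
points (mask pixels with a background 4-neighbour; pixels beyond the
border count as foreground), matches them within a distance tolerance
θ using Euclidean distance transforms, and takes the harmonic mean of
boundary precision and recall; θ defaults to 0.75 % of the image
diagonal, the usual contour-matching convention. Two empty boundaries
score 1, exactly one empty scores 0. Binarisation threshold defaults
to 0.5. All metrics are checked against exhaustive pixel/pair
enumeration oracles on random 6×6 instances.

## Synthetic phantoms

The generator emulates the shape statistics of three dataset regimes,
not their photometric realism: `blob` (one compact region whose radius
is a low-order Fourier series of angle, on a background with 0–6
distractor shapes controlled by `clutter_level`), `vessel` (a seeded
branching random walk drawn 1–3 px wide; foreground fraction stays
within (0.01, 0.25) at 64×64), and `lung_pair` (two mirrored smooth
regions with 0–2 interior holes each). Intensities follow a two-level
model — foreground 0.7, background 0.3, distractors in 0.4–0.6 —
plus Gaussian noise (σ = 0.05 by default) clipped to [0, 1]; these
values make the toy problems learnable in minutes on a CPU while still
requiring the network to ignore clutter rather than threshold. Edge
ground truth is the inner boundary band of the mask (mask minus its
4-connected erosion, width 1 by default) — real edge annotations do
not exist for derived labels, so this convention matches the metric
suite's boundary definition. Passing tests on phantoms demonstrates
that the architecture, losses and training loop work as specified;
they say nothing about accuracy on clinical images, which have texture,
contrast variation and annotation noise the intensity model omits.

Augmentation applies one jointly sampled geometric transform (flips,
rotation, integer translation) to image, mask and edge; masks use
nearest-neighbour interpolation and stay binary, rotations by
multiples of 90° are exact, translation pads images with their median
intensity and masks with background.

## Training pipeline

Defaults follow the published recipe: Adam with lr 2e-3 and betas
(0.5, 0.999), batch size 4, up to 300 epochs, 8:1:1 ratio split or
k-fold cross-validation (in k-fold mode, fold i tests on chunk i,
validates on chunk i+1, trains on the rest). No learning-rate schedule
is applied by default; a cosine option exists. The best checkpoint by
validation Dice is kept (no early stopping unless a target Dice is
set); checkpoints are single .npz archives embedding the full network
configuration, and loading verifies the configuration and every
parameter shape. All randomness flows from `global_seed` through named
sub-seeds (init, shuffling, augmentation), which makes split manifests
bitwise reproducible and training curves reproducible to
floating-point accuracy. A non-finite loss aborts with the epoch, step
and offending sample ids. For small datasets the ratio split
guarantees each part at least one sample.

The scaled-down experiment used by the test suite and the acceptance
script trains the default-width network on eight 64×64 blob phantoms
(batch 4, at most 200 steps, validation every 5 epochs on the same
held-in set, stopping at Dice ≥ 0.95); it converges in about 40 steps.
These sizes keep a full run within a few CPU-minutes while exercising
every module at the default widths.

## Known limitations

* Binary (single-foreground) segmentation of 2-D images only.
* The edge module's exact decoder injection point and the provenance
  of edge ground truth are interpretations documented above; the
  architecture description admits alternatives (both are exposed as
  configuration where meaningful).
* CPU-only NumPy compute: practical for the phantom scale, not for
  512×512 clinical training runs.
* Phantoms do not model texture, illumination gradients or annotator
  noise; metric values on them are not comparable to clinical
  benchmarks.
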