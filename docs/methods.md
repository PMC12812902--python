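# Methods

## The grading model

The unit of classification is one CLE examination: an ordered stream of
grayscale frames acquired at ~1 frame / 1.3 s. The model is a composition
of a per-frame visual encoder and a temporal head:

1. **Preprocessing.** Integer frames are mapped to [0, 1] by fixed-scale
   division with the dtype maximum (255 or 65535). Per-image min–max
   scaling is deliberately avoided: absolute fluorescein brightness is
   itself informative, and fixed-scale division keeps frames comparable.
   Frames are resized bilinearly (corner-aligned sampling disabled, i.e.
   `skimage.transform.resize` defaults) to the backbone's square input;
   non-square frames are resized aspect-preserving and padded at the
   median intensity, an estimate of the background level. Grayscale is
   replicated across three channels to satisfy RGB backbone contracts.
   Preprocessing never reorders, drops or duplicates frames; excluding a
   wholly artifact-ridden sequence is a curation decision upstream of this
   package.

2. **Visual backbone.** Each frame is encoded independently (frame-
   permutation equivariance holds by construction; temporal information
   enters only downstream). The backbone interface is pluggable; the
   self-contained `tiny_test_cnn` — three 3×3 stride-2 valid convolutions
   (8, 16, 32 channels) with ReLU, then global average pooling to a 32-d
   embedding — is the workhorse. Its weights are random but seeded, and it
   is used frozen: with standardization (below), random convolutional
   projections retain enough local structure for the temporal head to
   work with, and a frozen extractor keeps single-CPU training fast.
   Two of its design points matter:
   * *valid (unpadded) convolutions* — zero padding on a bright-background
     image fabricates strong frame-border edges that dominate class
     activation maps;
   * *per-frame mean centring of the input* — CLE content is a dark
     deviation from a bright background; centring lets rectified channels
     of either weight sign respond to silhouettes rather than to the
     background itself.
   ImageNet-pretrained families (Inception-ResNet-V2, ResNet50, VGG16,
   vision transformer) are accepted by the interface but require a local
   weight source; without one the package raises a clear error rather than
   attempting a download. Fine-tuning the backbone is not implemented:
   the temporal head is where the method lives, and frozen extraction
   keeps every experiment deterministic and cheap.

3. **Temporal head.** Backbone features are z-scored per dimension with
   statistics fitted on the training split (stored with the model), then
   linearly projected to the model width. Sinusoidal positional encoding
   `pe[p, 2i] = sin(p / 10000^(2i/D))`, `pe[p, 2i+1] = cos(...)` is added
   to the true (unpadded) positions; a learned position table is available
   as an option. Two post-norm transformer encoder blocks (multi-head
   self-attention + position-wise FFN, residual + layer norm) contextualize
   the sequence. A 1-D convolution along the temporal axis (odd kernel,
   'same' zero padding) captures local temporal patterns; masked global
   average pooling over the valid frames compresses the sequence into one
   global temporal embedding; a fully connected layer with softmax yields
   P(high), P(low).

4. **Padding contract.** Variable-length sequences are padded to the batch
   maximum with a boolean mask. Padded keys are additively masked out of
   attention (−10⁹ before softmax), padded frames are zeroed before the
   temporal convolution, and pooling divides by the true length — so the
   logits of a sequence are bit-for-bit independent of what it is batched
   with (asserted to 1e−5 in the tests).

5. **Frame-based baseline.** A small per-frame MLP head (32 hidden units)
   on the same frozen features, aggregated per examination by majority
   vote with ties broken toward high grade (the screening-oriented choice:
   a false high-grade call costs a biopsy; a false low-grade call can cost
   an undergraded tumor). A mean-probability rule is also available. The
   baseline is frame-permutation invariant — the property the sequence
   model deliberately gives up, and the axis along which the two are
   compared.

Class convention throughout: index 1 = high grade = the positive class.

## Training

Cross-entropy loss on softmax outputs (probability clamped at 1e−12 in the
scalar loss helper; the training path uses log-softmax directly), Adam
with β₁ = 0.9, β₂ = 0.999, ε = 1e−8. Train/test splits are random
partitions of the sequence manifest, stratified by grade label by default
(both classes must appear on both sides; a small unstratified split can
violate this by chance), with an optional case-level grouping that keeps
all sequences of one patient on one side to avoid case leakage.
Sequence-level splitting remains the default because it is the protocol
the per-split accuracy columns refer to. Train/test disjointness is
asserted before every fit, and a non-finite loss aborts with a diagnostic.
Everything — weight init, batch shuffling, dropout — is driven by explicit
seeds; identical seeds reproduce identical loss trajectories.

## The simulator

The generator reproduces the CLE image-formation phenomenology rather than
its physics:

* flat fluorescein background (default 0.6) plus Gaussian sensor noise
  (σ = 0.03), clipped to [0, 1] (never wrapped);
* tumor-cell silhouettes: anti-aliased filled ellipses darker than the
  background by the silhouette contrast (0.35), with Poisson-distributed
  count (density × area), Gaussian radius (pleomorphism = radius/
  eccentricity spread), static across all frames of a sequence;
* RBC silhouettes: uniform discs translating rigidly at a per-sequence
  flow direction and speed (px/frame); the frame is toroidal for all
  silhouettes — a shape crossing one edge re-enters opposite — which keeps
  silhouette counts exactly conserved and gives tumor cells and RBCs
  identical edge statistics (otherwise edge clipping leaks a per-frame
  intensity difference between confound classes);
* motion artifacts: whole-frame directional box blur (kernel = frame/8)
  applied to an independently flagged fraction of frames (default 0.5,
  the clinically reported artifact rate);
* optional high-grade extras: 1–3 irregular dark elliptical necrotic
  patches; bright branching random-walk curves for microvascular
  proliferation.

Default scene scale is 128 px, 30 frames (the corpus mean of ~30 images
per sequence), 1.3 s frame interval. The desk-scale experiment
configuration is 64 px × 10 frames with ~15 cells/frame — chosen so a full
train/evaluate cycle (80 sequences, backbone extraction, 100 epochs) runs
in seconds on one CPU.

Grade profiles override only generative parameters, never the seed. The
separated presets give the high grade 2.5× cell density, radius σ 1.6 px,
eccentricity σ 0.3, necrosis and vessels; the low grade has mild uniform
cellularity. The **RBC-confound preset** gives both grades the same
expected silhouette count (30 per 64² frame) and identical silhouette
geometry; in the high grade all silhouettes are static tumor cells, in the
low grade two thirds are RBCs flowing at 6 px/frame. Per-frame statistics
are then indistinguishable (the per-sequence count is Poisson(30) in both
classes), so any frame-level classifier sits at chance and only temporal
reasoning can separate the grades — a controlled, falsifiable version of
the static-tumor-vs-flowing-RBC distinction experts use.

What the simulator does **not** emulate: fluorescein pharmacokinetics and
wash-in/wash-out dynamics, probe-contact pressure effects, tissue
microarchitecture beyond cell silhouettes, device-specific optics, focus
drift. Passing benchmarks on simulated data therefore demonstrates that
the architecture can exploit temporal structure of this kind — not
clinical performance on patient streams.

## Class activation maps

Gradient-weighted CAM on the backbone's last convolutional block: channel
weights are the spatial means of the target-class logit gradient, the map
is the rectified weighted channel sum, min–max normalized to [0, 1]
(a constant map normalizes to all-zeros rather than dividing by zero) and
bilinearly upsampled to frame resolution. When the frame head was fitted
on standardized features, the same affine transform is inserted in the
differentiated graph. Overlays blend a warm-high colormap over the
grayscale frame at α = 0.45. CAMs are per-frame; temporal attribution
across frames is out of scope.

## Numerical choices

* Float64 throughout; gradients of every operator are validated against
  central finite differences at 1e−5.
* Softmax and log-softmax use the max-shift trick; the shift is treated as
  a constant, which is exact by shift invariance.
* Attention masking uses an additive −10⁹, which underflows to exactly
  zero weight after softmax for all practical score ranges.
* Split sizes use `round(train_fraction × N)` with largest-remainder
  allocation across strata so the total is exact.
* Display rounding of metrics is nearest-integer percent; full precision
  is retained internally and in JSON reports.
* Majority-vote ties break toward high grade; equal softmax probabilities
  also classify as high.

## Desk-scale experiment configuration

The two standard experiments (`clegrade.experiments`) use 16 cases × 5
sequences (80 sequences: 60 train / 20 test, stratified), the seeded
frozen `tiny_test_cnn`, a narrow temporal model (model_dim 32, 4 heads,
2 encoder blocks, FFN 64, conv kernel 3 × 32 channels, dropout 0), Adam at
5e−3 for 100 epochs, batch 10. The learning rate and epoch count were
chosen for reliable convergence of the small model; the wider defaults in
`TemporalModelConfig` (model_dim 128, FFN 256, dropout 0.1) are the
recommended starting point at realistic data scales.

## Known limitations

* The confound benchmark's sequence-model accuracy varies noticeably with
  the split/init seed (roughly 65–100% on 20 test sequences); the
  sequence-vs-frame gap is therefore reported as a median over seeds.
* Frozen random features are a deliberately weak visual encoder; absolute
  accuracies on the separated preset say little about the ceiling of the
  architecture with a pretrained backbone.
* The CAM localization property is validated on single-cluster scenes;
  multi-focal scenes would need per-component analysis rather than a
  single center of mass.
* `GradePrediction` for the majority-vote baseline reports the vote share
  as its probability, which is a calibration-free quantity.
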