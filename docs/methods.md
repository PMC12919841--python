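# Methods

This note records the modeling assumptions, parameter choices and numerical
conventions behind `cogattn`. The README covers usage; this document covers
*why* the package computes what it computes.

## 1. Attention blocks

Both blocks operate on a feature map `F ∈ R^{C×H×W}` and combine a channel
branch and a spatial branch.

**Channel branch.** Global average pooling (GAP) and global max pooling
(GMP) over the spatial axes produce two length-`C` descriptors. A shared
two-layer bottleneck MLP (`C → max(1, C/R) → C`, ReLU in the middle,
reduction ratio `R = 16` by default) maps each descriptor to channel logits.
The default fusion is `mlp_then_sum` — `MLP(GAP) + MLP(GMP)` — with
`sum_then_mlp` (`MLP(GAP + GMP)`) available as an ablation. The two fusions
coincide exactly when the MLP is linear on the descriptors' range and differ
in general; both behaviors are pinned by tests.

**Spatial branch.** GAP and GMP across the channel axis produce two `H×W`
maps, fused by elementwise sum into a single-channel map, then passed
through a `k×k` convolution (default `k = 7`) with dilation `d` (default 2)
and same padding `d(k−1)/2`, followed by batch normalization. Dilation
enlarges the receptive field to `k + (k−1)(d−1)` (13 at the defaults)
without extra parameters; `conv_mode="standard"` forces `d = 1` as an
ablation. Even kernel sizes are rejected because they admit no symmetric
same padding.

**Composition.**

* PCAB (parallel): `M_CS = σ(M_C ⊕ M_S)` (broadcast sum over C and H×W, a
  *single* sigmoid), output `F + F ⊙ M_CS`. Keeping the per-branch maps
  un-squashed before the sum is deliberate: squashing each branch first and
  then summing would push the joint gate toward saturation.
* SCAB (sequential): `F_C = F ⊙ σ(M_C(F))`, then the spatial map is
  recomputed *from the gated features*: output `F + F_C ⊙ σ(M_S(F_C))`.

Both are residual; since every gate lies in (0, 1), `|out| ≤ 2|F|`
elementwise and the zero map is a fixed point (given zero conv/BN biases).
Tests enforce shape preservation, the gain bound, and bit-level agreement
(to 1e−5) with an independent pure-Python loop oracle.

PCAB and SCAB have identical parameter counts per site; they differ only in
composition order. Whether the extra sequential nonlinearity helps is an
empirical question the benchmark addresses, not a structural one.

## 2. Backbones and insertion sites

* **ResNet18** — standard torchvision-compatible topology. With a 3-class
  head it has exactly 11,178,051 parameters (11.18 M); with a 1000-class
  head, 11,689,512, which is the canonical published count and serves as a
  cross-check. Attention sits after `conv2+bn2` of each basic block,
  *before* the shortcut addition, so the block gates only the residual
  branch; 8 sites with widths 64, 64, 128, 128, 256, 256, 512, 512.
* **MobileNetV4-Conv-Small** — reconstructed conv-only small variant: a
  32-wide stem, two fused stages, 12 universal inverted bottleneck (UIB)
  blocks at widths 96/128, a 1×1 expansion to 960, global pooling, a
  960→1280 head and the classifier. With 3 classes: 2,495,587 parameters
  (2.5 M to two significant figures). Attention sites are the stem and the
  12 UIB outputs.
* **MiniConvNet** — an 8/16/32-channel three-stage CNN for 64×64
  experiments; sites at the two deeper stages. This is the workhorse of the
  package's own benchmark because it trains in seconds per epoch on a CPU.

Insertion is expressed as a declarative `InsertionPlan` (kind, site paths,
channel widths, config) applied in place; an empty plan is the identity and
leaves the backbone bitwise unchanged.

## 3. Numerical engine

No deep-learning framework is used. `cogattn._tensor` implements a small
reverse-mode autodiff engine over numpy arrays: topological-order backward,
im2col + BLAS convolutions (with a shift-accumulate depthwise path), max
pooling with argmax routing, a fused batch-normalization primitive with the
standard analytic backward, and a fused, numerically stable
softmax-cross-entropy. Gradients of every primitive are verified against
central finite differences in float64; forward convolutions are verified
against `scipy.signal.correlate2d`.

Determinism: parameter initialization draws from a seeded generator
(`nn.manual_seed`), batch order from the training config seed, and the
synthetic generator derives one child generator per image from
`(dataset_seed, image_index)`, so datasets are reproducible elementwise and
independent of how many images are requested.

## 4. Complexity accounting

Costs are counted analytically from a shape-traced forward pass at batch
size 1, with the convention **1 MAC = 2 FLOPs**; batch norm, activations and
pooling are charged 1 FLOP per element, and bias additions 1 FLOP per output
element. Under this convention ResNet18 at 224×224 costs ≈1.82 GMACs,
matching the widely used published figure. Any layer type without a
registered rule raises rather than silently under-counting. Model size is
parameter count × element width (2/4/8 bytes).

## 5. Metrics and splits

Metrics come from explicit confusion matrices (rows = true, columns =
predicted). Binary reports use a designated positive class. Multi-class
reports are macro one-vs-rest averages; note that the macro "accuracy" (the
mean of per-class one-vs-rest accuracies) is *not* the overall trace
accuracy, which is exposed separately as `overall_accuracy`. Undefined
ratios (zero denominators) are reported as `None` with a warning, never as
0 or NaN. Fold aggregation uses the population standard deviation
(divisor `n`), the convention pinned by the reference value
`94.31 (±0.674)` for the folds {93.37, 94.76, 95.14, 94.61, 93.67}. Display
rounding is round-half-up, since two-decimal clinical metric tables
conventionally round 0.005 upward.

Holdout splitting is stratified 80/10/10 with per-class floor allocation
(train and validation take their floors, the remainder goes to test);
k-fold is stratified with per-class fold sizes differing by at most one.
Both are hand-rolled for full determinism and cross-checked against
scikit-learn's `StratifiedKFold` allocation guarantees in tests.

## 6. Synthetic microscopy generator

The generator emulates Giemsa-like stained single-WBC crops: a pale
background with smooth noise, an elliptical cytoplasm with a soft edge, a
nucleus whose boundary is perturbed by a low-order Fourier wobble
(irregularity), and chromatin texture inside the nucleus. The default
benchmark is two classes × 500 images at 64×64: a *blast-like* class (large
cell, high nucleus-to-cell ratio, irregular chromatin-rich nucleus) versus a
*lymphocyte-like* class (smaller, compact, round nucleus). The class
difference is deliberately driven by the same morphology features a
hematologist uses, and the rendered geometry is stored so tests can verify
separability (mean radius difference > 3 pooled standard errors) and
Grad-CAM mass against ground-truth cell masks.

What it does **not** emulate: optics (no point-spread function or focus
blur), staining variability across labs, touching/overlapping cell
boundaries, red-cell background clutter, or any real dataset's intensity
statistics. Results on this generator demonstrate that the pipeline works
and that attention is not harmful on a morphology-separable task; they say
nothing about clinical performance.

Augmentation mirrors a standard smear recipe: brightness 0.8–1.2, horizontal
and vertical flips, shifts up to ±0.2 of the image size, rotations up to
±45°, scaling 0.5–1.0, shear 0.1–0.9; `expand_dataset` grows a dataset with
augmented copies using largest-remainder per-class allocation and records
full provenance (source index and seed) per generated image.

## 7. Training protocol

SGD with momentum 0.9, learning rate 0.001 (constant), L2 weight decay
0.005, batch size 16, 30 epochs, cross-entropy loss; inputs scaled to
[0, 1], normalized to mean 0.5 / std 0.5 per channel, NCHW. The final-epoch
model is used by default; `select_best=True` restores the
best-validation-accuracy epoch instead. A non-finite loss aborts training
with an error immediately — divergence is never silently averaged away.

The package's own benchmark (used by the test suite and the acceptance
script) trains the MiniConvNet at 64×64 for 10 epochs on the 1000-image
synthetic benchmark over multiple seeds, with and without SCAB, comparing
mean held-out test accuracy. The problem size is chosen so the full
comparison completes in minutes on one CPU core; it is a scaled-down stand-in
for full 224×224 backbone training, which the code also supports but which
is not exercised in CI-scale runs.

## 8. Explainability

Grad-CAM: capture the activations and gradients at the last convolutional
stage (or any named layer), weight each channel by its spatially averaged
gradient for the target class, ReLU the weighted sum, bilinearly upsample to
the input size, and min–max normalize (constant maps normalize to zero
rather than dividing by zero). `heat_mass_in_mask` reports the fraction of
the top-decile heat inside a ground-truth cell mask as a localization
diagnostic. Per-channel feature maps are exposed through the same capture
mechanism.

## 9. Limitations

* The synthetic benchmark is much easier than real smear data; accuracy
  numbers obtained on it are not comparable to published clinical results.
* The numpy engine is CPU-only and single-threaded beyond BLAS; full
  224×224 training of ResNet18 is supported but slow, so desk-scale
  experiments use the mini backbone.
* MobileNetV4-Conv-Small is a faithful parameter-count reconstruction of
  the conv-small topology, but no pretrained weights are distributed, and
  `pretrained=True` is rejected explicitly.
* FLOPs/MACs follow one fixed convention (Section 4); tools that charge BN
  or pooling differently will report different totals for the same model.
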