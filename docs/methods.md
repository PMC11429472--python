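# Methods

## Problem and model

Fundus tumors (uveal melanoma foremost among them) appear in retinal
photographs as single lesions whose areas span more than an order of
magnitude and whose boundaries are irregular. `fundusseg` implements an
encoder–decoder segmentation network built around three ideas:

1. **A multiscale input pyramid.** One RGB image `I ∈ R^{3×H×W}` is
   rearranged losslessly into three scales: `I1 = I`,
   `I2 ∈ R^{48×H/4×W/4}` (block-4 space-to-depth, channel-replicated to 96
   to match the mid-branch stem) and `I3 ∈ R^{192×H/8×W/8}` (block-8).
   Space-to-depth is the only operator consistent with these channel
   counts (48 = 3·4², 192 = 3·8²): each b×b spatial tile moves into b²
   channel slots, and the rearrangement is exactly invertible, so no
   information is lost before encoding.

2. **Three encoder branches of one common output width.**
   `F1 = Enc1(I1)` is a Swin-style hierarchical windowed-attention branch
   (Tiny geometry: depths 2/2/6/2, heads 3/6/12/24, window 7, widths
   96/192/384/768); `F2 = Enc2(I2)` is a ConvNeXt-style branch whose
   stage-1 downsampling is replaced by a 1×1 convolution + layer norm so
   that it can consume the already-quarter-resolution `I2`;
   `F3 = Enc3(I3)` omits stage 1 entirely and enters stage 2 through the
   same 1×1-conv stem. All three end at `768×H/32×W/32`, asserted at every
   forward pass. Convolutional blocks follow the V2 recipe (7×7 depthwise
   conv → LN → 4× pointwise expansion → GELU → global response
   normalisation → pointwise reduction, residual); a flag switches to
   V1-style layer scale. At full width the branches carry 27.5M / 27.9M /
   27.6M parameters, within 3% of the published Tiny variants.

3. **Channel-attention fusion.** The side branches are gated
   squeeze-and-excitation style — `F̄k = σ(conv1×1(GAP(Fk))) ⊗ Fk` — and
   summed into the center branch: `F = F1 + F̄2 + F̄3`. The two gates have
   separate parameters; as the equations state a single 1×1 convolution,
   there is no reduction bottleneck by default (an optional flag restores
   the classic C→C/r→C form). No nonlinearity precedes the sigmoid.

4. **Decoder with projected, summed skips.** `F` is restored to
   `F′ ∈ R^{3×H×W}` by four blocks of 1×1 conv → transposed conv → 1×1
   conv with channel plan [384, 192, 96, 3]. The first three blocks
   upsample 2× with 3×3 stride-2 transposed convolutions; since the
   channel plan has four entries but five resolution levels separate H/32
   from H, the last block covers H/4 → H in one 4×4 stride-4 transposed
   convolution. A 4×4 kernel (not 3×3) is used for that step because a
   3×3 kernel at stride 4 leaves every fourth output row and column with
   no kernel support — bias-only stripes; the 4×4 kernel tiles the output
   exactly. After each of the first three blocks, the encoder stage maps
   at the matching resolution are concatenated across branches
   ([Enc1, Enc2, Enc3] order, fixed for checkpoint determinism), projected
   back to the decoder width by a 1×1 convolution, and summed into the
   stream — this reading makes "skips are summed" and "branch maps are
   concatenated and re-projected" simultaneously true. At H/4 only Enc1
   and Enc2 contribute (Enc3 starts at H/8). No skip exists at H/32.

5. **Classification-driven prompt dynamic head.** A two-layer MLP
   (C→256→2, softmax) classifies the pooled fused features as benign or
   malignant. The class fills the fixed template
   `"it is a image of {lesion class}"` (class names "benign tumor" /
   "malignant tumor"; the template's grammar is kept as is), and a frozen
   text encoder embeds the sentence into 512 dimensions. The pooled
   features concatenated with the embedding (proF, length C+512) pass
   through three linear layers (hidden 256, ReLU between) that emit a flat
   vector of 113 numbers — the kernels and biases, layer by layer and
   weights before bias, of a per-image 1×1 convolution chain 3→8→8→1
   (ReLU between layers, sigmoid output) applied to `F′`. The chain
   widths are a design choice in the spirit of CLIP-driven dynamic heads;
   the head depth (three convolutions) and the 1×1 controller inputs are
   fixed by the architecture. One sigmoid channel (rather than two-channel
   softmax) keeps the head minimal and pairs naturally with the Dice
   terms.

### Training objective

`L = λ1·L_ce + λ2·L_dice + λ2·L_boundary_dice + λ_cls·L_cls` with
λ1 = λ2 = λ_cls = 1 by default (no published values exist; all are
config). The same λ2 deliberately weights both Dice terms; an optional
λ3 overrides the boundary weight so all four loss-ablation configurations
(CE only, CE+Dice, CE+boundary, all) are reachable by config alone.

* `L_ce` is binary cross-entropy averaged over pixels (the one-channel
  sigmoid form of the categorical cross-entropy).
* `L_dice = 1 − (2Σyp + ε)/(Σy + Σp + ε)` with ε = 1e-6 in numerator and
  denominator, so empty-vs-empty scores 0.
* `L_boundary_dice` is the Dice loss on boundary rings `y′ = dilate(y) − y`
  and `p′ = dilate(p) − p`. **Sign convention:** the ring is dilation
  minus original (the outer boundary), which is nonnegative for inputs in
  [0, 1]; the reverse order is nonpositive everywhere and degenerate on
  binary masks. Dilation is an iterated 3×3 window maximum (stride 1,
  zero padding) — exact morphological dilation on binary masks, and
  differentiable almost everywhere for soft predictions, so the term
  trains without pre-thresholding. On ties the subgradient follows the
  first argument of the pairwise maximum.
* `L_cls` is cross-entropy on the classifier softmax. The classifier is
  trained jointly (single optimizer, single backward pass), not with a
  separate optimization.

During training the prompt is filled with the ground-truth class (teacher
forcing), decoupling head training from early classifier noise; at
inference the classifier argmax drives the identical code path.

### Optimisation schedule

AdamW (decoupled weight decay 0.01 — unpublished, the optimizer's
conventional default) starting at lr 2e-4, batch 12 at full scale. The
rate halves when the best epoch training loss has not strictly improved
for 20 consecutive epochs; training stops when the rate reaches the 5e-7
floor or when 50 consecutive epochs pass without a rate reduction. Both
windows are config. The schedule is epoch-level and uses the training
loss (no validation split is prescribed). Note the 50-epoch rule as
stated terminates even while the loss is still improving — it is an
aggressive cap, and long desk-scale runs set `no_reduction_stop_epochs`
to the epoch budget instead.

### Evaluation

Per-image IoU `|X∩Y|/|X∪Y|` and Dice `2|X∩Y|/(|X|+|Y|)` on masks
binarised at 0.5, reported as macro means ± sample (n−1) standard
deviation across images ("mIoU m±s / mDice m±s", 4 decimals). Two
conventions the formulas leave open: an empty prediction on an empty
reference scores 1.0 (a correct empty mask is perfect), and the spread is
across images, not training reruns.

## Numerical stack

No deep-learning framework is used: the package carries a compact
reverse-mode autodiff engine over NumPy arrays (`fundusseg.autograd`) and
a small layer library (`fundusseg.nn`). Pointwise convolutions are
batched matrix products; depthwise and strided convolutions are
shift-and-add sums over kernel offsets; transposed convolutions
zero-interleave and correlate with the flipped kernel, with output sizes
asserted (never silently cropped — a geometry mismatch raises). Windowed
attention uses the standard shifted-window additive mask; maps whose side
is not a multiple of the window are zero-padded for attention and cropped
back. Arrays are float32 (float64 passes through, which the
finite-difference tests exploit); sigmoid uses the numerically stable
`expit`; softmax subtracts a detached max. Linear/attention weights are
truncated-normal (std 0.02), convolutions He-scaled; initialisation,
shuffling and augmentation all derive from one seed, so training is
bit-reproducible.

## Synthetic data

The generator emulates the statistical structure of a 254-image clinical
fundus-tumor cohort, not its appearance: a dark circular fundus field
with a smooth illumination gradient, 2–6 quadratic-curve vessel-like
strokes, and exactly one connected lesion per image. Lesions are
star-shaped regions `r(θ) = R(1 + Σ_k a_k sin(kθ + φ_k))`, k = 2…6,
|a_k| ≤ 0.35 with Σ|a_k| ≤ 0.6 — irregular and non-convex but guaranteed
connected. Area fractions are log-uniform over [0.015, 0.27], the
fractions implied by the cohort's printed lesion-size bounds at its
native resolution (287,061 and 5,000,119 pixels at 4304×4306); the
class balance defaults to the cohort's 40.55% benign. Malignant lesions
get stronger boundary perturbation and a darker core so the image-level
class is learnable — a modelling convenience with no clinical meaning.
Generation is a pure function of (config, index); images are quantised
to 8-bit steps so PNG round-trips are exact.

What passing tests on this data do **not** show: robustness to camera
noise, multiple or diffuse lesions, vessel-lesion confusion, or any
real-pathology texture. The generator exists so the architecture, losses
and training loop are exercised end to end offline; claims about clinical
images require clinical data.

## Problem sizes

Full-scale geometry (448-pixel inputs, full Tiny widths) is exercised as
a single seeded forward pass. Training demonstrations use the
quarter-width model on 64-pixel images (window 4): eight synthetic images
are memorised to train mDice ≥ 0.8 within 200 epochs at learning rate
1e-3 (the package's desk-scale default; small widths tolerate — and
converge faster at — a higher rate than the full-scale 2e-4). The
estimator's defaults are this desk-scale configuration; the full-scale
setting is `image_size=448, micro_scale=1, window_size=7,
learning_rate=2e-4, batch_size=12`.

## Known limitations

* Branches initialise randomly; loading published pretrained backbone
  weights is out of scope, so absolute segmentation quality on real data
  is not comparable to fine-tuned systems.
* The built-in text encoder is a deterministic hash embedding — it gives
  the prompt path distinct, reproducible class vectors but no semantics.
  A real CLIP text tower can be injected (any callable `str → vector`
  with a `dim` attribute); it is treated as frozen either way.
* The 3×3-at-stride-4 reading of the final decoder block is rejected on
  coverage grounds (see above); if exact architectural parity with a
  reference implementation matters, this is the one deliberate deviation.
* Single-process CPU execution only; no mixed precision, no multi-GPU.
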