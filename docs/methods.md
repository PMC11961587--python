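# Methods

This note records how the model is defined, which knobs matter, what the
synthetic data does and does not emulate, and where the design was
genuinely open and a choice had to be made.

## Model definition

### Grouped multi-scale attention (GMSA)

The input `[B, c, h, w]` is partitioned along channels into `G` groups
(equal widths unless `group_widths` is given).  Per group `i`:

1. linear projections to queries/keys/values at full resolution;
2. **tokenization** at scale `s_i`: non-overlapping average pooling of
   the spatial map onto an `s_i × s_i` grid, patch size
   `(h/s_i, w/s_i)`, token count `N_i = s_i²`.  When `h` or `w` is not
   a multiple of `s_i`, the map is edge-padded bottom/right up to the
   next multiple before pooling, and the padding is cropped again after
   step 4;
3. multi-head scaled-dot-product attention over the `N_i` tokens
   (`heads_per_group` defaults to `max(1, d_i/32)`; all heads in a
   group share the group's scale);
4. **detokenization**: each attended token is broadcast
   (nearest-neighbor) back over its source patch;
5. a per-group linear output projection; groups are concatenated.

Open points resolved here, as this package's own choices: average
pooling is the tokenizer (parameter-free, exactly invertible on
patch-constant inputs, which gives a crisp unit test); queries are
tokenized at `s_i` like keys/values — only then does the advertised
`O(s_i⁴ d_i)` attention-score cost hold; the output projection is per
group (mirroring standard attention practice); no positional encoding
is added, position information enters through the convolutional LPU.
The attention-score multiply count is also *measured*: an instrumented
counter accumulates `N²·d` per forward pass, and the log–log slope over
`s ∈ {2,4,8}` is 4 by construction and by measurement.

A configured `s_i` larger than a stage's resolution cannot produce a
token grid; the low-level layer treats it as a configuration error,
while the model builder clamps each `s_i` to the stage resolution so
that small-input configurations (e.g. 64 px images, stage-4 maps of
2 px) remain usable with the standard scale lists.

### Inter-scale attention (ISA)

ISA exchanges information across the channel groups at cost linear in
the token count `N = h·w`.  Per group: channel affinity
`CA_i = softmax_tokens(k_i)ᵀ v_i ∈ R^{d_g×d_g}`.  The affinities are
global-average-pooled to one scalar each, passed through a two-layer
gate network (reduction ratio 2, GELU between — a GELU rather than a
ReLU because the bottleneck can be a single unit, and a dead ReLU there
would sever the gate from the gradient graph) and a sigmoid, giving
gates `γ_i ∈ (0,1)`.  The gated affinities are fused across the group
axis by a learned linear combination into one shared map `A`, and every
group's output is `softmax_channels(q_i) · A`, concatenated and
reshaped back.

Two ambiguities were resolved deliberately: the affinity is the
`KᵀV`-ordered channel–channel product (the `[d_g, d_g]` shape and the
linear-in-N cost force this ordering under a row-token layout), and
gating is applied *before* the across-group fusion (gating after would
make the per-group gates indistinguishable from a single global scale).
Softmax axes follow the efficient channel-attention family: over tokens
for K, over channels for Q.

### Encoder

A 7×7 stride-4 convolution (plus batch norm) embeds the image at
stride 4.  Each of the four stages runs one Local Perception Unit

    LPU(X) = Skip(X) + Proj(SE(DWConv(Conv(Norm(X)))))

(batch norm → 1×1 expansion with BN+GELU → 3×3 depthwise with BN+GELU,
stride 2 when the stage downsamples → squeeze–excitation → 1×1 shrink;
the skip is the identity within a stage and average-pool + 1×1
projection when downsampling), followed by `L_i` MSEAU blocks, each
four pre-norm residual sub-blocks: GMSA, FFN, ISA, FFN.  Pre-norms are
layer normalization over channels (transformer convention); the FFN is
a pointwise two-layer expansion (default ratio 4).  With circular
padding and no downsampling the LPU is exactly translation-equivariant,
which the test suite verifies — that is the design motivation for
pairing convolutions with the attention blocks.

Stage widths and depths are configuration, defaulting to
`C = [64, 128, 256, 512]`, `L = [2, 2, 2, 2]`; the published model's
exact widths are not part of this implementation's contract, so
parameter-count parity is out of scope.

### Decoder

The deepest encoder map enters the decoder directly (its fusion partner
does not exist yet) and passes Inception + CSA refinement.  Every
shallower level: bilinear ×2 upsampling and a 1×1 channel reduction of
the running state, a Context Perception Block
(`x' = conv(SE(concat(enc, dec)))`, `gate = sigmoid(conv(dec))`,
`out = enc + gate ⊙ x'` — a residual on the encoder stream), an
Inception block (1×1, 3×3, 5×5-as-two-3×3, and smoothed-pool branches,
concatenated and projected), and a CSA block (SE-style channel gate,
then a spatial gate from the channel-mean statistic through a 7×7 conv
and sigmoid; the spatial conv uses replicate padding so a uniform map
keeps a uniform gate).  Auxiliary 1×1 heads tap the stride-8/16/32
decoder states.  The stride-4 state is fused with two image stems
(3×3 conv-BN-ReLU at full resolution; a second stride-2 block computed
from the first) through upsample+concat+conv fusions, avoiding a blunt
4× upsample of the coarse logits.  CSA internals and the spatial
statistic (mean, not mean+max) are this package's reading of a
figure-level description.

### Loss

Per branch: `0.3·CE + 0.7·soft-Dice`.  The Dice term is probabilistic
with smoothing `ε = 1e-5`, averaged uniformly over classes (background
included) and batch; crisp inputs recover the set formula as `ε → 0`.
Deep supervision weights the main and stride-8/16/32 branches
`0.7/0.1/0.1/0.1`; auxiliary logits are bilinearly upsampled to the
label resolution rather than downsampling the labels, so one-pixel
structures are never aliased out of the target.

## Numerical engine

There is no GPU framework in the dependency set; the package carries a
small reverse-mode autodiff engine on numpy (float32) with the
primitives the network needs — broadcast arithmetic, batched matmul,
im2col convolutions (dense and depthwise), pooling, padding
(zero/edge/wrap), bilinear resizing as two interpolation-matrix
products, and the usual nonlinearities (GELU is the exact erf form;
the sigmoid is the numerically stable two-branch form).  Gradients are
verified against central finite differences; a finite-difference step
of 1e-2 is used there because float32 forward values make smaller
steps rounding-dominated.  Optimizers are Adam and momentum SGD.

One mathematical fine point: a group with `s = 1` has a single token,
its attention weight is identically 1, and the gradient to that group's
query/key projections is *exactly zero* — correctly so.  The
gradient-liveness check therefore runs on an all-`s ≥ 2` configuration,
where every parameter must (and does) receive gradient after one step.

## Synthetic data

Scenes contain a "large-organ" class (1–2 ellipses, semi-axes 12–20 px
at the 64 px reference size) and a "small-lesion" class (2–5 ellipses,
semi-axes 2–4 px), placed without overlap by rejection sampling (whole
scenes are resampled a bounded number of times before an explicit
packing error), on a dark background (intensity 0.2) with Gaussian
noise σ = 0.05.  Radii scale linearly with image size.  **Both
foreground classes share the same intensity distribution (0.75 ± 0.08
per-object jitter): object scale and context are the only cues that
separate them.**  That is deliberate — the generator exists to provide
multi-scale signal, and an intensity shortcut would let a pointwise
classifier solve the task.  Per-class mean object areas differ by well
over the 10× spread the multi-scale design targets.

What the generator does *not* emulate: imaging physics (CT/MRI noise
spectra, bias fields, partial-volume effects), anatomical shape priors,
texture, and inter-slice structure.  Passing the end-to-end tests shows
the architecture can learn scale-dependent labeling and that the whole
pipeline (data → training → metrics → significance report) is wired
correctly; it says nothing about clinical performance on real scans.

Images are quantized to the 8-bit grid at generation time, so the PNG
round trip is bit-exact; masks are 8-bit label images; a JSON manifest
records cases and a 70/10/20 train/val/test split; NIfTI export is
optional.

## Training defaults and the desk-scale study

`RunConfig` defaults mirror the reference recipe: batch size 12, Adam
(lr 1e-4, weight decay 1e-4) or SGD (lr 0.05, momentum 0.9, weight
decay 1e-4), constant learning rate, optional early stopping on
validation Dice.  Epoch counts and schedules are not part of the
recipe and default conservatively.

The bundled reference experiment (`scaleformer.experiments`) uses a
deliberately small footprint chosen once for a single CPU core: 200
scenes of 64×64 with 3 classes; a tiny model (channels
[16, 32, 64, 128], depths [1, 1, 1, 1], FFN ratio 2, LPU expansion 2);
Adam at lr 1e-3 (the reference 1e-4 is tuned for full-size runs and is
needlessly slow at this scale), batch 8, 12 epochs.  The multi-scale
variant uses the standard scale lists `[1,2,4,7]/[1,2,4,7]/[1,7]/[1,7]`
(clamped where a stage map is smaller than a scale); the single-scale
ablation assigns every group within a stage the same scale
(`[7,7,7,7]/[4,4,4,4]/[2,2]/[2,2]`).  Both runs share the data seed and
the comparison is a paired t-test over per-case test Dice.

## Evaluation metrics

DSC is reported in percent, per class; empty-vs-empty is defined as
100.  HD95 pools the directed boundary distances from both masks before
taking the linearly interpolated 95th percentile (boundary = mask pixel
with a 4-neighbor outside the mask, image border counting as outside);
coordinates are scaled by the pixel spacing.  An empty mask yields the
image diagonal as a flagged worst case — never a silent zero — so
averages stay defined.  mIoU/Acc/Sen/Spe come from the binary confusion
matrix, with zero-denominator ratios reported as missing rather than 0.
The paired t-test is two-sided at α = 0.05, with 95% mean confidence
intervals reported for both score vectors; the report supports Dice in
fraction or percent form, whichever the caller supplies.

## Known limitations

- CPU-only: a full-size (224 px, [64,128,256,512]-channel) training run
  is far slower than with a GPU framework; the engine is intended for
  reference, testing and desk-scale experiments.
- 2D slices only; no 3D volumetric variant.
- No pretrained weights, no parameter/FLOP parity with any published
  configuration (stage widths/depths of the published model are not
  specified anywhere reproducible).
- Batch-norm statistics come from the small desk-scale batches; very
  small batch sizes can make evaluation-mode behavior noisy.
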