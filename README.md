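# scaleformer

A self-contained implementation of a grouped multi-scale attention
encoder–decoder for 2D medical image segmentation, together with the
evaluation metrics (DSC, HD95, mIoU/Acc/Sen/Spe), a paired-significance
report, and a seeded synthetic multi-scale dataset generator, so the
whole pipeline trains and evaluates at desk scale on one CPU with no
external data.

## Who this is for

Medical images mix structures whose sizes differ by an order of
magnitude — a liver and a gallbladder, a cardiac ventricle and a thin
myocardial rim, a large lesion and a small one.  Plain self-attention
layers see the image at one token granularity, so a single layer cannot
simultaneously resolve the small structures and summarize the large
ones.  This package is for people who want a *tested, inspectable*
implementation of the channel-grouped answer to that problem: readable
reference code, exhaustive brute-force oracles for every block, and a
synthetic testbed where object scale is the only class cue.

## The model

**GMSA (grouped multi-scale attention).**  A `[B, c, h, w]` feature map
is split into `G` channel groups of widths `d_i`.  Group *i* is
projected to `Q_i, K_i, V_i = x_i W^Q_i, x_i W^K_i, x_i W^V_i`, pooled
onto an `s_i × s_i` token grid (patch size `(h/s_i, w/s_i)`, token count
`N_i = s_i²`), attends with `softmax(Q Kᵀ/√d_h) V`, and the attended
tokens are broadcast back over their patches.  Attention-score cost per
group is `O(N_i² d_i) = O(s_i⁴ d_i)`, so one layer mixes cheap global
groups (`s=1` is a single global token) with finer-grained groups
(`s=7` keeps 49 tokens), totalling `O(Σ s_i⁴ d_i)`.

**ISA (inter-scale attention).**  After GMSA the groups have never
talked to each other.  ISA forms per-group channel affinities
`CA_i = softmax_tokens(k_i)ᵀ v_i` (cost linear in token count), pools
each to a scalar, gates the affinities with a sigmoid feed-forward
network, fuses them into one shared map `A` across the group axis, and
applies `softmax_channels(q_i) · A` per group — cross-scale exchange at
linear cost.

**Architecture.**  A 7×7/stride-4 patch-embedding stem feeds four
stages (strides 4/8/16/32; 56/28/14/7 px at 224 input).  Each stage is
one convolutional Local Perception Unit
`LPU(X) = Skip(X) + Proj(SE(DWConv(Conv(Norm(X)))))` followed by `L_i`
MSEAU blocks (pre-norm residual GMSA → FFN → ISA → FFN).  The decoder
walks back up with Context Perception Blocks (gated encoder/decoder
fusion), Inception refinement and channel+spatial attention, merges two
full/half-resolution image stems, and emits main logits at input
resolution plus auxiliary logits at strides 8/16/32.

**Loss.**  Each branch is scored with `0.3·CE + 0.7·soft-Dice`; the
four branches are weighted `0.7/0.1/0.1/0.1` (auxiliaries upsampled to
label resolution).

## Worked example

```python
import json
import numpy as np
from scaleformer import (SceneSpec, generate_dataset, GMSAConfig, gmsa_cost,
                         dsc, hd95, paired_t_test)

# 1. a seeded multi-scale dataset: big "organ" ellipses + tiny "lesions"
samples = generate_dataset(SceneSpec(image_size=64, num_classes=3, seed=42), 5)
areas = {c: int((samples[0].mask == c).sum()) for c in (1, 2)}
print("pixel areas in scene 0 (class 1 = organ, class 2 = lesion):", areas)

# 2. what does one GMSA layer cost at stage-1 resolution 56x56?
cost = gmsa_cost(GMSAConfig(64, [1, 2, 4, 7]), 56)
print([g["tokens"] for g in cost["groups"]], cost["total_attention_mults"])

# 3. score a deliberately shifted mask
gt = samples[0].mask == 1
pred = np.roll(gt, 2, axis=1)
print(f"DSC = {dsc(pred, gt):.2f}%  HD95 = {hd95(pred, gt):.2f} px")

# 4. compare two models' per-case Dice with a paired t-test
rng = np.random.default_rng(0)
ours = 0.90 + 0.02 * rng.standard_normal(20)
baseline = ours - 0.012 + 0.01 * rng.standard_normal(20)
rep = paired_t_test(ours, baseline)
print(f"t = {rep.t_stat:.4f}, p = {rep.p_value:.4f}, "
      f"significant = {rep.significant}")
```

prints

```
pixel areas in scene 0 (class 1 = organ, class 2 = lesion): {1: 920, 2: 153}
[1, 4, 16, 49] 42784
DSC = 92.83%  HD95 = 2.00 px
t = 7.1209, p = 0.0000, significant = True
```

The token counts `[1, 4, 16, 49]` are the `N_i = s_i²` sequence for the
default stage-1 scales `[1, 2, 4, 7]`, and 42784 multiply-accumulates is
the layer's `Σ s_i⁴ d_i` attention-score budget — group `s=7` alone
accounts for 38416 of them, which is why large scales live only in
shallow stages.  The shifted organ mask loses ~7 Dice points and sits 2
boundary pixels off; the paired t-test finds the 1.2-point Dice gap
between the two synthetic model score vectors highly significant.

## Command line

```bash
scaleformer generate --out data/ --n 200 --classes 3 --seed 42 --size 64
scaleformer train    --data data/ --out run/ --seed 42
scaleformer eval     --checkpoint run/checkpoint.npz --data data/ \
                     --out run/eval --compare other_run/checkpoint.npz
scaleformer predict  --checkpoint run/checkpoint.npz --out preds/ data/*_image.png
```

`eval` writes a per-case metrics CSV, aggregate JSON, and — when
`--compare` is given — a paired t-test report (JSON + CSV with method,
t, p, significance and 95% confidence intervals).

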