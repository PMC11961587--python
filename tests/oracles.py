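"""Independent brute-force reference implementations used as test oracles.

Everything here is plain numpy (float64), written step by step from the
block definitions, with naive loops where that keeps the code obviously
correct.  Nothing imports the package's autodiff path, so agreement
between these functions and the library is a genuine dual-route check.
"""

import numpy as np
from scipy.special import erf


def gelu(x):
    return 0.5 * x * (1.0 + erf(x / np.sqrt(2.0)))


def softmax(x, axis=-1):
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def edge_pad_br(x, s):
    """Pad the trailing two axes up to the next multiple of s by
    replicating the last row/column (bottom/right only)."""
    H, W = x.shape[-2:]
    Hp = -(-H // s) * s
    Wp = -(-W // s) * s
    pads = [(0, 0)] * (x.ndim - 2) + [(0, Hp - H), (0, Wp - W)]
    return np.pad(x, pads, mode="edge")


def ref_tokenize(x, s):
    """[B,d,H,W] -> [B,s*s,d] by block averaging (row-major grid)."""
    x = edge_pad_br(np.asarray(x, dtype=np.float64), s)
    B, d, Hp, Wp = x.shape
    ph, pw = Hp // s, Wp // s
    tokens = np.zeros((B, s * s, d))
    for r in range(s):
        for c in range(s):
            patch = x[:, :, r * ph:(r + 1) * ph, c * pw:(c + 1) * pw]
            tokens[:, r * s + c, :] = patch.mean(axis=(2, 3))
    return tokens


def ref_detokenize(tokens, s, H, W):
    tokens = np.asarray(tokens, dtype=np.float64)
    B, N, d = tokens.shape
    Hp = -(-H // s) * s
    Wp = -(-W // s) * s
    ph, pw = Hp // s, Wp // s
    out = np.zeros((B, d, Hp, Wp))
    for r in range(s):
        for c in range(s):
            out[:, :, r * ph:(r + 1) * ph, c * pw:(c + 1) * pw] = \
                tokens[:, r * s + c, :][:, :, None, None]
    return out[:, :, :H, :W]


def ref_attention(q, k, v, heads):
    """Naive multi-head softmax(QK^T/sqrt(dh))V on [B,N,d]."""
    q, k, v = (np.asarray(a, dtype=np.float64) for a in (q, k, v))
    B, N, d = q.shape
    dh = d // heads
    out = np.zeros_like(q)
    for b in range(B):
        for h in range(heads):
            sl = slice(h * dh, (h + 1) * dh)
            scores = q[b, :, sl] @ k[b, :, sl].T / np.sqrt(dh)
            out[b, :, sl] = softmax(scores, axis=-1) @ v[b, :, sl]
    return out


def _linear(module, x):
    w = module.weight.data.astype(np.float64)
    b = module.bias.data.astype(np.float64) if module.bias is not None else 0.0
    return x @ w + b


def ref_gmsa(x, module):
    """Step-by-step grouped multi-scale attention using module weights."""
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    outs, start = [], 0
    for g, (d, s, heads) in enumerate(zip(module.widths, module.scales,
                                          module.heads)):
        xg = x[:, start:start + d]
        start += d
        flat = xg.reshape(B, d, H * W).transpose(0, 2, 1)
        q = _linear(module.q_proj[g], flat).transpose(0, 2, 1).reshape(B, d, H, W)
        k = _linear(module.k_proj[g], flat).transpose(0, 2, 1).reshape(B, d, H, W)
        v = _linear(module.v_proj[g], flat).transpose(0, 2, 1).reshape(B, d, H, W)
        att = ref_attention(ref_tokenize(q, s), ref_tokenize(k, s),
                            ref_tokenize(v, s), heads)
        spatial = ref_detokenize(att, s, H, W)
        flat_out = spatial.reshape(B, d, H * W).transpose(0, 2, 1)
        proj = _linear(module.out_proj[g], flat_out)
        outs.append(proj.transpose(0, 2, 1).reshape(B, d, H, W))
    return np.concatenate(outs, axis=1)


def ref_isa(x, module):
    """Step-by-step inter-scale attention using module weights."""
    x = np.asarray(x, dtype=np.float64)
    B, C, H, W = x.shape
    g = module.cfg.num_groups
    d = C // g
    flat = x.reshape(B, C, H * W).transpose(0, 2, 1)      # B,N,C
    q = _linear(module.q_proj, flat)
    k = _linear(module.k_proj, flat)
    v = _linear(module.v_proj, flat)
    affinities = []
    for i in range(g):
        ki = k[:, :, i * d:(i + 1) * d]
        vi = v[:, :, i * d:(i + 1) * d]
        k_soft = softmax(ki, axis=1)                      # over tokens
        affinities.append(np.einsum("bnd,bne->bde", k_soft, vi))
    pooled = np.stack([ca.mean(axis=(1, 2)) for ca in affinities], axis=1)
    h = gelu(pooled @ module.gate_fc1.weight.data.astype(np.float64)
             + module.gate_fc1.bias.data.astype(np.float64))
    gates = 1.0 / (1.0 + np.exp(-(h @ module.gate_fc2.weight.data.astype(np.float64)
                                  + module.gate_fc2.bias.data.astype(np.float64))))
    mixw = module.mix_weight.data.astype(np.float64)
    A = sum(mixw[i] * affinities[i] * gates[:, i][:, None, None]
            for i in range(g)) + float(module.mix_bias.data[0])
    outs = []
    for i in range(g):
        qi = q[:, :, i * d:(i + 1) * d]
        outs.append(softmax(qi, axis=2) @ A)
    fused = np.concatenate(outs, axis=2)                  # B,N,C
    return fused.transpose(0, 2, 1).reshape(B, C, H, W)


# ------------------------------------------------------------------
# naive convolution / normalization building blocks
# ------------------------------------------------------------------

def naive_conv2d(x, w, b=None, stride=1, padding=0):
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    out = np.zeros((B, O, Ho, Wo))
    for y in range(Ho):
        for xx in range(Wo):
            patch = x[:, :, y * stride:y * stride + kh,
                      xx * stride:xx * stride + kw]
            out[:, :, y, xx] = np.tensordot(patch, w, axes=([1, 2, 3],
                                                            [1, 2, 3]))
    if b is not None:
        out += np.asarray(b, dtype=np.float64)[None, :, None, None]
    return out


def naive_depthwise(x, w, b=None, stride=1, padding=0):
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    B, C, H, W = x.shape
    _, kh, kw = w.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    out = np.zeros((B, C, Ho, Wo))
    for y in range(Ho):
        for xx in range(Wo):
            patch = x[:, :, y * stride:y * stride + kh,
                      xx * stride:xx * stride + kw]
            out[:, :, y, xx] = (patch * w[None]).sum(axis=(2, 3))
    if b is not None:
        out += np.asarray(b, dtype=np.float64)[None, :, None, None]
    return out


def ref_batchnorm(x, bn):
    x = np.asarray(x, dtype=np.float64)
    mean = x.mean(axis=(0, 2, 3), keepdims=True)
    var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
    normed = (x - mean) / np.sqrt(var + bn.eps)
    return normed * bn.weight.data.astype(np.float64)[None, :, None, None] \
        + bn.bias.data.astype(np.float64)[None, :, None, None]


def ref_se(x, se):
    pooled = x.mean(axis=(2, 3))
    h = np.maximum(_linear(se.fc1, pooled), 0.0)
    gate = 1.0 / (1.0 + np.exp(-_linear(se.fc2, h)))
    return x * gate[:, :, None, None]


def ref_lpu(x, lpu):
    """Sequential evaluation of Skip(X) + Proj(SE(DWConv(Conv(Norm(X)))))."""
    x = np.asarray(x, dtype=np.float64)
    h = ref_batchnorm(x, lpu.norm)
    h = naive_conv2d(h, lpu.conv_expand.weight.data, lpu.conv_expand.bias.data)
    h = gelu(ref_batchnorm(h, lpu.bn1))
    h = naive_depthwise(h, lpu.dwconv.weight.data, lpu.dwconv.bias.data,
                        stride=2 if lpu.downsample else 1, padding=1)
    h = gelu(ref_batchnorm(h, lpu.bn2))
    h = ref_se(h, lpu.se)
    h = naive_conv2d(h, lpu.proj.weight.data, lpu.proj.bias.data)
    if lpu.skip_proj is None:
        skip = x
    else:
        base = x
        if lpu.downsample:
            B, C, H, W = x.shape
            base = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
        skip = naive_conv2d(base, lpu.skip_proj.weight.data,
                            lpu.skip_proj.bias.data)
    return skip + h


def ref_hd95(pred, gt, spacing=(1.0, 1.0)):
    """Exhaustive all-pairs boundary-distance HD95 (and full Hausdorff).

    A mask pixel is boundary if any 4-neighbor lies outside the mask,
    counting out-of-image as outside.  Returns (hd95, hd_max).
    """
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    sp = np.asarray(spacing, dtype=float)

    def boundary(mask):
        pts = []
        H, W = mask.shape
        for i in range(H):
            for j in range(W):
                if not mask[i, j]:
                    continue
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < H and 0 <= nj < W) or not mask[ni, nj]:
                        pts.append((i, j))
                        break
        return np.array(pts, dtype=float)

    bp = boundary(pred) * sp
    bg = boundary(gt) * sp
    dists = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([dists.min(axis=1), dists.min(axis=0)])
    return float(np.percentile(pooled, 95)), float(pooled.max())
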