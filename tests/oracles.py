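"""Independent nested-loop reference implementations of the blocks.

These follow the blocks' defining equations literally with scalar loops and
explicit matrix arithmetic, sharing nothing with the package's im2col /
einsum / autograd execution path.  They are only meant for tiny inputs
(<= 8x8) where O(everything) loops are affordable.
"""

from __future__ import annotations

import numpy as np


def sigmoid_ref(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def relu_ref(x):
    return np.maximum(x, 0.0)


def conv2d_ref(x, w, b=None, dilation=1, padding=None):
    """Dense-loop stride-1 cross-correlation with zero padding."""
    bsz, cin, h, wid = x.shape
    cout, cin_w, kh, kw = w.shape
    assert cin == cin_w
    if padding is None:
        padding = (dilation * (kh - 1) // 2, dilation * (kw - 1) // 2)
    ph, pw = padding
    xp = np.zeros((bsz, cin, h + 2 * ph, wid + 2 * pw))
    xp[:, :, ph:ph + h, pw:pw + wid] = x
    ho = h + 2 * ph - dilation * (kh - 1)
    wo = wid + 2 * pw - dilation * (kw - 1)
    out = np.zeros((bsz, cout, ho, wo))
    for n in range(bsz):
        for co in range(cout):
            for i in range(ho):
                for j in range(wo):
                    acc = 0.0
                    for ci in range(cin):
                        for u in range(kh):
                            for v in range(kw):
                                acc += (w[co, ci, u, v]
                                        * xp[n, ci, i + u * dilation, j + v * dilation])
                    out[n, co, i, j] = acc + (b[co] if b is not None else 0.0)
    return out


def avgpool2_ref(x):
    bsz, c, h, w = x.shape
    out = np.zeros((bsz, c, h // 2, w // 2))
    for i in range(h // 2):
        for j in range(w // 2):
            out[:, :, i, j] = x[:, :, 2 * i:2 * i + 2, 2 * j:2 * j + 2].mean(axis=(2, 3))
    return out


def bilinear_ref(x, size):
    """Scalar-loop separable bilinear resize, align_corners=False."""
    bsz, c, h, w = x.shape
    ho, wo = size

    def coords(n_in, n_out, i):
        src = (i + 0.5) * n_in / n_out - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        return lo, hi, src - lo

    out = np.zeros((bsz, c, ho, wo))
    for i in range(ho):
        r0, r1, fr = coords(h, ho, i)
        for j in range(wo):
            c0, c1, fc = coords(w, wo, j)
            out[:, :, i, j] = ((1 - fr) * (1 - fc) * x[:, :, r0, c0]
                               + (1 - fr) * fc * x[:, :, r0, c1]
                               + fr * (1 - fc) * x[:, :, r1, c0]
                               + fr * fc * x[:, :, r1, c1])
    return out


def _wb(unit):
    """Extract (weight, bias) arrays from a ConvUnit built with norm=False."""
    w = unit.conv.weight.data
    b = unit.conv.bias.data if unit.conv.bias is not None else None
    return w, b


def calibrated_ref(block, x):
    """Literal dual-branch calibrated convolution (normalisation disabled)."""
    half = x.shape[1] // 2
    x1, x2 = x[:, :half], x[:, half:]

    t = relu_ref(conv2d_ref(x1, *_wb(block.local)))
    d = relu_ref(conv2d_ref(t, *_wb(block.wide), dilation=block.wide.conv.dilation))
    y1 = relu_ref(conv2d_ref(np.concatenate([d, t], axis=1), *_wb(block.mix)))

    g = conv2d_ref(avgpool2_ref(x2), *_wb(block.low))  # gating conv: no ReLU
    gate = sigmoid_ref(bilinear_ref(g, x2.shape[2:]) + x2)
    f = relu_ref(conv2d_ref(x2, *_wb(block.feat)))
    y2 = relu_ref(conv2d_ref(f * gate, *_wb(block.out)))
    return np.concatenate([y1, y2], axis=1)


def fusion_ref(block, x_high, y_low):
    """Literal symmetric-fusion skip block (normalisation disabled)."""
    full = y_low.shape[2:]
    x1 = relu_ref(conv2d_ref(bilinear_ref(x_high, full), *_wb(block.x1_proj)))
    x2 = relu_ref(conv2d_ref(x_high, *_wb(block.x2_conv)))
    y1 = relu_ref(conv2d_ref(avgpool2_ref(y_low), *_wb(block.y1_proj)))
    y2 = relu_ref(conv2d_ref(y_low, *_wb(block.y2_conv)))
    gate = sigmoid_ref(bilinear_ref(conv2d_ref(x2 + y1, *_wb(block.gate)), full))
    main = relu_ref(conv2d_ref(x1 + y2, *_wb(block.main)))
    return main * gate + y_low


def attention_ref(att, a):
    """Explicit matrix-arithmetic sigmoid self-attention (norm disabled)."""
    bsz, c, h, w = a.shape
    n = h * w
    cr = att.reduced
    q = conv2d_ref(a, *_wb(att.query)).reshape(bsz, cr, n)        # gating: no ReLU
    k = conv2d_ref(a, *_wb(att.key)).reshape(bsz, cr, n)
    v = relu_ref(conv2d_ref(a, *_wb(att.value))).reshape(bsz, cr, n)
    out = np.zeros_like(a)
    for bi in range(bsz):
        s = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                s[i, j] = sigmoid_ref(np.dot(q[bi, :, i], k[bi, :, j]))
        attended = np.zeros((cr, n))
        for ci in range(cr):
            for i in range(n):
                attended[ci, i] = np.dot(s[i], v[bi, ci])
        attended = attended.reshape(1, cr, h, w)
        weight = relu_ref(conv2d_ref(attended, *_wb(att.out)))
        out[bi] = a[bi] * weight[0]
    return out


def dilated_attention_ref(block, x):
    """Literal multi-branch dilated-attention bottleneck (norm disabled)."""
    bsz, c, h, w = x.shape
    pooled = x.mean(axis=(2, 3), keepdims=True)
    x1 = bilinear_ref(relu_ref(conv2d_ref(pooled, *_wb(block.pool_proj))), (h, w))
    s = x + x1
    x2 = relu_ref(conv2d_ref(s, *_wb(block.point)))
    branches = []
    for conv, att in zip(block.dilated, block.attend):
        bd = relu_ref(conv2d_ref(s, *_wb(conv), dilation=conv.conv.dilation))
        branches.append(attention_ref(att, bd))
    cat = np.concatenate([x1, x2] + branches, axis=1)
    return relu_ref(conv2d_ref(cat, *_wb(block.fuse)))
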