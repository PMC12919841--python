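"""Independent straight-line references for the attention computations.

Everything here is written with explicit Python loops over indices and
plain scalar arithmetic (no call into the package's tensor engine), so it
can serve as an oracle for the block forwards.  It is deliberately slow and
only meant for small (C, H, W).
"""

import math

import numpy as np


def ref_channel_pool(F):
    C, H, W = F.shape
    avg = np.zeros(C)
    mx = np.full(C, -np.inf)
    for c in range(C):
        s = 0.0
        for h in range(H):
            for w in range(W):
                v = float(F[c, h, w])
                s += v
                if v > mx[c]:
                    mx[c] = v
        avg[c] = s / (H * W)
    return avg, mx


def ref_spatial_pool(F):
    C, H, W = F.shape
    avg = np.zeros((H, W))
    mx = np.full((H, W), -np.inf)
    for h in range(H):
        for w in range(W):
            s = 0.0
            for c in range(C):
                v = float(F[c, h, w])
                s += v
                if v > mx[h, w]:
                    mx[h, w] = v
            avg[h, w] = s / C
    return avg, mx


def ref_mlp(v, W1, b1, W2, b2):
    hidden = []
    for i in range(W1.shape[0]):
        s = float(b1[i])
        for j in range(len(v)):
            s += float(W1[i, j]) * float(v[j])
        hidden.append(max(s, 0.0))
    out = []
    for i in range(W2.shape[0]):
        s = float(b2[i])
        for j in range(len(hidden)):
            s += float(W2[i, j]) * hidden[j]
        out.append(s)
    return np.array(out)


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def ref_channel_map(F, params, sigmoid, mode="avg_plus_max",
                    fusion="mlp_then_sum"):
    avg, mx = ref_channel_pool(F)
    W1, b1, W2, b2 = (params["fc1.weight"], params["fc1.bias"],
                      params["fc2.weight"], params["fc2.bias"])
    if mode == "avg_only":
        out = ref_mlp(avg, W1, b1, W2, b2)
    elif mode == "max_only":
        out = ref_mlp(mx, W1, b1, W2, b2)
    elif fusion == "sum_then_mlp":
        out = ref_mlp(avg + mx, W1, b1, W2, b2)
    else:
        out = ref_mlp(avg, W1, b1, W2, b2) + ref_mlp(mx, W1, b1, W2, b2)
    if sigmoid:
        out = np.array([_sigmoid(v) for v in out])
    return out


def ref_conv_same(x, kernel, bias, dilation):
    """Single-channel same-padding dilated cross-correlation, loop form."""
    H, W = x.shape
    k = kernel.shape[0]
    pad = dilation * (k - 1) // 2
    out = np.zeros((H, W))
    for h in range(H):
        for w in range(W):
            s = bias
            for i in range(k):
                for j in range(k):
                    hh = h + i * dilation - pad
                    ww = w + j * dilation - pad
                    if 0 <= hh < H and 0 <= ww < W:
                        s += float(kernel[i, j]) * float(x[hh, ww])
            out[h, w] = s
    return out


def ref_spatial_map(F, params, sigmoid, mode="avg_plus_max", eps=1e-5):
    avg, mx = ref_spatial_pool(F)
    if mode == "avg_only":
        desc = avg
    elif mode == "max_only":
        desc = mx
    else:
        desc = avg + mx
    kernel = params["spatial_conv.weight"][0, 0]
    bias = float(params.get("spatial_conv.bias", [0.0])[0])
    d = params["dilation"]
    conv = ref_conv_same(desc, kernel, bias, d)
    gamma = float(params["spatial_bn.weight"][0])
    beta = float(params["spatial_bn.bias"][0])
    rm = float(params["spatial_bn.running_mean"][0])
    rv = float(params["spatial_bn.running_var"][0])
    out = (conv - rm) / math.sqrt(rv + eps) * gamma + beta
    if sigmoid:
        out = np.vectorize(_sigmoid)(out)
    return out


def ref_pcab(F, params, mode="avg_plus_max", fusion="mlp_then_sum"):
    C, H, W = F.shape
    mc = ref_channel_map(F, params, sigmoid=False, mode=mode, fusion=fusion)
    ms = ref_spatial_map(F, params, sigmoid=False, mode=mode)
    out = np.zeros_like(F, dtype=np.float64)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                mcs = _sigmoid(float(mc[c]) + float(ms[h, w]))
                out[c, h, w] = F[c, h, w] + F[c, h, w] * mcs
    return out


def ref_scab(F, params, mode="avg_plus_max", fusion="mlp_then_sum"):
    C, H, W = F.shape
    mc = ref_channel_map(F, params, sigmoid=True, mode=mode, fusion=fusion)
    fc = np.zeros_like(F, dtype=np.float64)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                fc[c, h, w] = F[c, h, w] * float(mc[c])
    ms = ref_spatial_map(fc, params, sigmoid=True, mode=mode)
    out = np.zeros_like(F, dtype=np.float64)
    for c in range(C):
        for h in range(H):
            for w in range(W):
                out[c, h, w] = F[c, h, w] + fc[c, h, w] * float(ms[h, w])
    return out


def block_params(block):
    """Extract a block's arrays into the plain dict the references expect."""
    state = block.state_dict()
    params = {k: np.asarray(v, dtype=np.float64) for k, v in state.items()}
    params["dilation"] = block.spatial_conv.dilation
    if block.spatial_conv.bias is None:
        params["spatial_conv.bias"] = np.array([0.0])
    return params


def randomize_block(block, rng):
    """Give a block nontrivial weights, biases and batch-norm statistics."""
    for _, p in block.named_parameters():
        p.data = rng.normal(0.0, 0.5, size=p.data.shape).astype(np.float32)
    block.spatial_bn._set_buffer(
        "running_mean", rng.normal(0.0, 0.3, size=1).astype(np.float32))
    block.spatial_bn._set_buffer(
        "running_var", rng.uniform(0.5, 1.5, size=1).astype(np.float32))
    return block
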