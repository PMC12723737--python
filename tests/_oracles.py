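"""Independent brute-force oracles for the network stages.

These are written straight from the mathematical definitions (explicit loops,
one output element at a time) and share no code with the implementation they
check.
"""

import numpy as np


def oracle_conv(params, window_sizes, x):
    """Direct sliding-window convolution sum, one output position at a time."""
    dim, L = x.shape
    out = np.zeros((dim, L))
    for w in window_sizes:
        W, b = params[f"conv{w}_W"], params[f"conv{w}_b"]
        left = w // 2
        for l in range(L):
            acc = np.zeros(dim)
            for j in range(w):
                src = l - left + j
                if 0 <= src < L:
                    acc += W[j] @ x[:, src]
            out[:, l] += acc + b
    return out


def oracle_featuremap(params, slope, x):
    """Explicit per-column matrix products."""
    dim, L = x.shape
    out = np.zeros_like(x)
    for l in range(L):
        h = params["fm_W1"] @ x[:, l] + params["fm_b1"]
        h = np.where(h > 0, h, slope * h)
        out[:, l] = params["fm_W2"] @ h + params["fm_b2"]
    return out


def oracle_attention(params, x):
    """Brute-force per-head softmax-and-sum."""
    n_head = params["att_wk"].shape[0]
    dim, L = x.shape
    weights, feats = [], []
    for h in range(n_head):
        v = params["att_Wv"][h] @ x + params["att_bv"][h][:, None]
        k = params["att_wk"][h] @ x + params["att_bk"][h]
        q = params["att_wq"][h] @ x + params["att_bq"][h]
        logits = q * k
        e = np.exp(logits - logits.max())
        w = e / e.sum()
        weights.append(w)
        feats.append(sum(w[l] * v[:, l] for l in range(L)))
    return np.array(weights), np.array(feats)


def oracle_residual(W, b, slope, x):
    z = W @ x + b
    return x + np.where(z > 0, z, slope * z)
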