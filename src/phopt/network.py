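"""The optimal-pH regression network.

Architecture (applied to a per-residue embedding matrix ``r`` of shape
(dim, L)):

1. **Multi-scale 1-D CNN** — one length-preserving convolution per sliding
   window size (default 1..5), outputs summed element-wise.
2. **Linear featuremap** — position-wise 2-layer map dim -> 2*dim -> dim.
3. **Multi-head multiplicative self-attention** — per head, pointwise
   projections give values v (dim x L), keys k (1 x L) and queries q (1 x L);
   the attention weights are ``w = softmax(q * k)`` (element-wise product over
   positions, no scaling); the head feature is the weight-averaged value
   ``x = sum_l w_l v[:, l]`` and all heads are concatenated.
4. **Residual dense blocks** — ``x + LeakyReLU(W x + b)`` at width
   n_head * dim, repeated n_rd times.
5. **Linear head** — a scalar on the pH/14 scale.

Everything is plain NumPy. Each stage has a hand-derived backward pass
(verified against finite differences in the test suite), so the model trains
with no deep-learning framework. Batches of variable-length sequences are
zero-padded with a boolean mask; masked positions are zeroed after the CNN and
receive -inf attention logits, which makes padding provably inert.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embed import Embedder, embed_batch, embed_sequence
from .exceptions import ContractError
from .io import ProteinRecord

CHECKPOINT_FORMAT_VERSION = 1

#: Scale factor between the network output and pH units.
PH_SCALE = 14.0


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the selected configuration: 4 attention heads, 4 residual
    dense blocks, convolution window sizes 1-5 and an embedding dimension of
    320 (the small ESM-2 model); ``dim`` is set smaller in tests.
    """

    dim: int = 320
    n_head: int = 4
    n_rd: int = 4
    window_sizes: tuple[int, ...] = (1, 2, 3, 4, 5)
    leaky_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1 or self.n_head < 1 or self.n_rd < 1:
            raise ContractError("dim, n_head and n_rd must all be >= 1")
        if not self.window_sizes or any(w < 1 for w in self.window_sizes):
            raise ContractError("window_sizes must be non-empty, all >= 1")
        object.__setattr__(self, "window_sizes", tuple(self.window_sizes))

    @property
    def pooled_dim(self) -> int:
        return self.n_head * self.dim


@dataclass
class AttentionResult:
    """Attention weights and pooled features for one sequence (or a batch).

    ``weights`` rows are simplex vectors over the unmasked positions: each
    head's weights are non-negative and sum to 1; masked positions carry
    exactly zero weight.
    """

    weights: np.ndarray            # (n_head, L) or (B, n_head, L)
    per_head_features: np.ndarray  # (n_head, dim) or (B, n_head, dim)
    pooled: np.ndarray             # (n_head*dim,) or (B, n_head*dim)
    mask: np.ndarray | None = None


@dataclass
class ModelState:
    """A model configuration plus all learned parameter arrays."""

    config: ModelConfig
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "ModelState":
        return ModelState(self.config,
                          {k: v.copy() for k, v in self.params.items()})


def _leaky(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def _leaky_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, 1.0, slope)


def init_state(config: ModelConfig) -> ModelState:
    """Seeded uniform fan-in initialization of every parameter array."""
    rng = np.random.default_rng(config.seed)
    d, h = config.dim, config.n_head
    D = config.pooled_dim

    def uni(shape, fan_in):
        a = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-a, a, size=shape)

    p: dict[str, np.ndarray] = {}
    for w in config.window_sizes:
        p[f"conv{w}_W"] = uni((w, d, d), w * d)
        p[f"conv{w}_b"] = np.zeros(d)
    p["fm_W1"] = uni((2 * d, d), d)
    p["fm_b1"] = np.zeros(2 * d)
    p["fm_W2"] = uni((d, 2 * d), 2 * d)
    p["fm_b2"] = np.zeros(d)
    p["att_Wv"] = uni((h, d, d), d)
    p["att_bv"] = np.zeros((h, d))
    p["att_wk"] = uni((h, d), d)
    p["att_bk"] = np.zeros(h)
    p["att_wq"] = uni((h, d), d)
    p["att_bq"] = np.zeros(h)
    for j in range(config.n_rd):
        p[f"rd{j}_W"] = uni((D, D), D)
        p[f"rd{j}_b"] = np.zeros(D)
    p["head_w"] = uni((D,), D)
    p["head_b"] = np.zeros(())
    return ModelState(config, p)


# ---------------------------------------------------------------------------
# batched forward / backward stages
# ---------------------------------------------------------------------------

def _conv_pads(w: int) -> tuple[int, int]:
    # length-preserving: symmetric for odd windows, extra zero on the left
    # for even windows so all scales align for the element-wise sum
    left = w // 2
    return left, (w - 1) - left


def _conv_forward(state: ModelState, x: np.ndarray, mask: np.ndarray):
    B, d, L = x.shape
    out = np.zeros_like(x)
    for w in state.config.window_sizes:
        W, b = state.params[f"conv{w}_W"], state.params[f"conv{w}_b"]
        left, right = _conv_pads(w)
        xpad = np.pad(x, ((0, 0), (0, 0), (left, right)))
        for j in range(w):
            out += np.einsum("oi,bil->bol", W[j], xpad[:, :, j:j + L])
        out += b[None, :, None]
    out *= mask[:, None, :]
    return out, (x, mask)


def _conv_backward(state: ModelState, cache, g: np.ndarray):
    x, mask = cache
    g = g * mask[:, None, :]
    B, d, L = x.shape
    dx = np.zeros_like(x)
    grads: dict[str, np.ndarray] = {}
    for w in state.config.window_sizes:
        W = state.params[f"conv{w}_W"]
        left, right = _conv_pads(w)
        xpad = np.pad(x, ((0, 0), (0, 0), (left, right)))
        dxpad = np.zeros_like(xpad)
        dW = np.empty_like(W)
        for j in range(w):
            xs = xpad[:, :, j:j + L]
            dW[j] = np.einsum("bol,bil->oi", g, xs)
            dxpad[:, :, j:j + L] += np.einsum("oi,bol->bil", W[j], g)
        grads[f"conv{w}_W"] = dW
        grads[f"conv{w}_b"] = g.sum(axis=(0, 2))
        dx += dxpad[:, :, left:left + L]
    return dx, grads


def _featuremap_forward(state: ModelState, x: np.ndarray):
    p = state.params
    s = state.config.leaky_slope
    h_pre = np.einsum("oi,bil->bol", p["fm_W1"], x) + p["fm_b1"][None, :, None]
    h = _leaky(h_pre, s)
    y = np.einsum("oi,bil->bol", p["fm_W2"], h) + p["fm_b2"][None, :, None]
    return y, (x, h_pre, h)


def _featuremap_backward(state: ModelState, cache, g: np.ndarray):
    x, h_pre, h = cache
    p = state.params
    s = state.config.leaky_slope
    grads = {
        "fm_W2": np.einsum("bol,bil->oi", g, h),
        "fm_b2": g.sum(axis=(0, 2)),
    }
    dh = np.einsum("oi,bol->bil", p["fm_W2"], g)
    dh_pre = dh * _leaky_grad(h_pre, s)
    grads["fm_W1"] = np.einsum("bol,bil->oi", dh_pre, x)
    grads["fm_b1"] = dh_pre.sum(axis=(0, 2))
    dx = np.einsum("oi,bol->bil", p["fm_W1"], dh_pre)
    return dx, grads


def _attention_forward(state: ModelState, x: np.ndarray, mask: np.ndarray):
    if not mask.any(axis=1).all():
        raise ContractError("attention requires at least one unmasked position "
                            "per sequence")
    p = state.params
    B, d, L = x.shape
    v = np.einsum("hoi,bil->bhol", p["att_Wv"], x) + p["att_bv"][None, :, :, None]
    k = np.einsum("hi,bil->bhl", p["att_wk"], x) + p["att_bk"][None, :, None]
    q = np.einsum("hi,bil->bhl", p["att_wq"], x) + p["att_bq"][None, :, None]
    logits = np.where(mask[:, None, :], q * k, -np.inf)
    zmax = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - zmax)
    w = e / e.sum(axis=-1, keepdims=True)
    xh = np.einsum("bhl,bhol->bho", w, v)
    pooled = xh.reshape(B, -1)
    return pooled, w, xh, (x, v, k, q, w, mask)


def _attention_backward(state: ModelState, cache, dpooled: np.ndarray):
    x, v, k, q, w, mask = cache
    p = state.params
    B, h, d, L = v.shape
    dxh = dpooled.reshape(B, h, d)
    dw = np.einsum("bho,bhol->bhl", dxh, v)
    dv = w[:, :, None, :] * dxh[:, :, :, None]
    dlogits = w * (dw - (dw * w).sum(axis=-1, keepdims=True))
    dq = dlogits * k
    dk = dlogits * q
    grads = {
        "att_Wv": np.einsum("bhol,bil->hoi", dv, x),
        "att_bv": dv.sum(axis=(0, 3)),
        "att_wk": np.einsum("bhl,bil->hi", dk, x),
        "att_bk": dk.sum(axis=(0, 2)),
        "att_wq": np.einsum("bhl,bil->hi", dq, x),
        "att_bq": dq.sum(axis=(0, 2)),
    }
    dx = (np.einsum("hoi,bhol->bil", p["att_Wv"], dv)
          + np.einsum("hi,bhl->bil", p["att_wk"], dk)
          + np.einsum("hi,bhl->bil", p["att_wq"], dq))
    return dx, grads


def _residual_forward(state: ModelState, pooled: np.ndarray):
    p = state.params
    s = state.config.leaky_slope
    cache = []
    out = pooled
    for j in range(state.config.n_rd):
        z = out @ p[f"rd{j}_W"].T + p[f"rd{j}_b"]
        cache.append((out, z))
        out = out + _leaky(z, s)
    return out, cache


def _residual_backward(state: ModelState, cache, g: np.ndarray):
    p = state.params
    s = state.config.leaky_slope
    grads: dict[str, np.ndarray] = {}
    for j in reversed(range(state.config.n_rd)):
        inp, z = cache[j]
        dz = g * _leaky_grad(z, s)
        grads[f"rd{j}_W"] = dz.T @ inp
        grads[f"rd{j}_b"] = dz.sum(axis=0)
        g = g + dz @ p[f"rd{j}_W"]
    return g, grads


def forward_batch(state: ModelState, r: np.ndarray, mask: np.ndarray):
    """Full batched forward pass.

    Parameters
    ----------
    r : (B, dim, L) zero-padded embedding batch
    mask : (B, L) boolean, True at real positions

    Returns
    -------
    (predictions, attention, cache): predictions are on the pH/14 scale,
    shape (B,); cache feeds :func:`backward_batch`.
    """
    if r.ndim != 3 or r.shape[1] != state.config.dim:
        raise ContractError(f"expected (B, {state.config.dim}, L) embeddings, "
                            f"got {r.shape}")
    if r.shape[2] < 1:
        raise ContractError("sequence length must be >= 1")
    c, conv_cache = _conv_forward(state, r, mask)
    f, fm_cache = _featuremap_forward(state, c)
    pooled, weights, xh, att_cache = _attention_forward(state, f, mask)
    res, rd_cache = _residual_forward(state, pooled)
    y = res @ state.params["head_w"] + state.params["head_b"]
    attn = AttentionResult(weights=weights, per_head_features=xh,
                           pooled=pooled, mask=mask)
    cache = (conv_cache, fm_cache, att_cache, rd_cache, res)
    return y, attn, cache


def backward_batch(state: ModelState, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of a scalar loss wrt every parameter, given d(loss)/d(y)."""
    conv_cache, fm_cache, att_cache, rd_cache, res = cache
    p = state.params
    grads = {"head_w": dy @ res, "head_b": np.asarray(dy.sum())}
    g = dy[:, None] * p["head_w"][None, :]
    g, rd_grads = _residual_backward(state, rd_cache, g)
    g, att_grads = _attention_backward(state, att_cache, g)
    g, fm_grads = _featuremap_backward(state, fm_cache, g)
    _, conv_grads = _conv_backward(state, conv_cache, g)
    for d in (rd_grads, att_grads, fm_grads, conv_grads):
        grads.update(d)
    return grads


def mse_loss_and_grads(state: ModelState, r: np.ndarray, mask: np.ndarray,
                       targets: np.ndarray):
    """Mean-squared-error loss on scaled targets plus parameter gradients."""
    y, _, cache = forward_batch(state, r, mask)
    resid = y - targets
    loss = float(np.mean(resid ** 2))
    dy = 2.0 * resid / len(resid)
    return loss, backward_batch(state, cache, dy)


# ---------------------------------------------------------------------------
# single-sequence operations
# ---------------------------------------------------------------------------

def _single(x: np.ndarray, mask: np.ndarray | None):
    d, L = x.shape
    if mask is None:
        mask = np.ones(L, dtype=bool)
    return x[None], np.asarray(mask, dtype=bool)[None]


def multi_scale_cnn(state: ModelState, r: np.ndarray,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Sum of length-preserving 1-D convolutions over all window sizes."""
    xb, mb = _single(r, mask)
    out, _ = _conv_forward(state, xb, mb)
    return out[0]


def linear_featuremap(state: ModelState, x: np.ndarray) -> np.ndarray:
    """Position-wise dim -> 2*dim -> dim map (LeakyReLU between layers)."""
    xb = x[None]
    out, _ = _featuremap_forward(state, xb)
    return out[0]


def self_attention(state: ModelState, x: np.ndarray,
                   mask: np.ndarray | None = None) -> AttentionResult:
    """Multiplicative key-query attention pooling for one sequence."""
    xb, mb = _single(x, mask)
    pooled, weights, xh, _ = _attention_forward(state, xb, mb)
    return AttentionResult(weights=weights[0], per_head_features=xh[0],
                           pooled=pooled[0], mask=mb[0])


def residual_dense_block(state: ModelState, x: np.ndarray,
                         block_index: int) -> np.ndarray:
    """One width-preserving block: ``x + LeakyReLU(W x + b)``."""
    p = state.params
    z = x @ p[f"rd{block_index}_W"].T + p[f"rd{block_index}_b"]
    return x + _leaky(z, state.config.leaky_slope)


def forward(state: ModelState, r: np.ndarray,
            mask: np.ndarray | None = None) -> tuple[float, AttentionResult]:
    """Full pipeline for one sequence; prediction is on the pH/14 scale."""
    xb, mb = _single(r, mask)
    y, attn, _ = forward_batch(state, xb, mb)
    return float(y[0]), AttentionResult(weights=attn.weights[0],
                                        per_head_features=attn.per_head_features[0],
                                        pooled=attn.pooled[0],
                                        mask=mb[0])


def predict_ph(state: ModelState, record: ProteinRecord | str,
               embedder: Embedder, clamp: bool = True) -> float:
    """Predicted optimal pH (14 x network output, clamped to [0, 14])."""
    r = embed_sequence(embedder, record)
    y, _ = forward(state, r)
    ph = PH_SCALE * y
    return float(np.clip(ph, 0.0, PH_SCALE)) if clamp else float(ph)


def predict_batch(state: ModelState, records, embedder: Embedder,
                  batch_size: int = 64, clamp: bool = True,
                  return_attention: bool = False):
    """Predict optimal pH for many sequences, batching by padded chunks."""
    preds = np.empty(len(records))
    attns: list[AttentionResult] = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        r, mask = embed_batch(embedder, chunk)
        y, attn, _ = forward_batch(state, r, mask)
        preds[start:start + len(chunk)] = y
        if return_attention:
            for i in range(len(chunk)):
                L = int(mask[i].sum())
                attns.append(AttentionResult(
                    weights=attn.weights[i, :, :L],
                    per_head_features=attn.per_head_features[i],
                    pooled=attn.pooled[i],
                    mask=mask[i, :L]))
    preds = PH_SCALE * preds
    if clamp:
        preds = np.clip(preds, 0.0, PH_SCALE)
    return (preds, attns) if return_attention else preds


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Write config + parameters to a single .npz archive (bit-exact reload)."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": {
            "dim": state.config.dim,
            "n_head": state.config.n_head,
            "n_rd": state.config.n_rd,
            "window_sizes": list(state.config.window_sizes),
            "leaky_slope": state.config.leaky_slope,
            "seed": state.config.seed,
        },
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state.params)


def load_checkpoint(path: str | Path) -> ModelState:
    with np.load(path) as npz:
        meta = json.loads(str(npz["__meta__"]))
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ContractError(
                f"checkpoint format {meta['format_version']} not supported")
        cfg = meta["config"]
        cfg["window_sizes"] = tuple(cfg["window_sizes"])
        config = ModelConfig(**cfg)
        params = {k: npz[k] for k in npz.files if k != "__meta__"}
    return ModelState(config, params)
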