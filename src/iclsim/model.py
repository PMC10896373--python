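"""Causal transformer in NumPy with manual backpropagation.

The network is a decoder-style self-attention stack (pre-layer-norm,
learned positional embeddings, ReLU feedforward of twice the hidden size)
that performs in-context learning in its forward pass and in-weight
learning through explicit gradient updates.  Backpropagation recomputes
each layer's internals during the backward sweep so peak memory stays
proportional to a single layer.

An :class:`AblationSpec` inhibits attention to whole in-context study
examples with probability ``p_a`` per example: dropped examples are removed
from the attention targets (keys) at every layer and head, for every query
position except the dropped tokens themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from iclsim import _kernels as K
from iclsim.encoding import Episode

LN_EPS = 1e-5


@dataclass(frozen=True)
class ModelConfig:
    d_v: int
    n_layers: int = 4
    n_heads: int = 8
    hidden_size: int = 64
    max_sequence_length: int = 128
    dropout: float = 0.0
    emb_init_scale: float = 1.0
    pos_encoding: str = "learned"  # or "rope" (rotary, Llama-style)
    pos_init: str = "sinusoid"  # or "random"
    pos_init_scale: float = 0.3
    qk_init: str = "identity"  # or "random"
    circuit_init: bool = False  # rope only: warm-start previous-token heads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size % self.n_heads != 0:
            raise ValueError(
                f"n_heads={self.n_heads} must divide hidden_size={self.hidden_size}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")

    @property
    def ffn_size(self) -> int:
        return 2 * self.hidden_size

    def to_dict(self) -> dict:
        return {
            "d_v": self.d_v,
            "n_layers": self.n_layers,
            "n_heads": self.n_heads,
            "hidden_size": self.hidden_size,
            "max_sequence_length": self.max_sequence_length,
            "dropout": self.dropout,
            "emb_init_scale": self.emb_init_scale,
            "pos_encoding": self.pos_encoding,
            "pos_init": self.pos_init,
            "pos_init_scale": self.pos_init_scale,
            "qk_init": self.qk_init,
            "circuit_init": self.circuit_init,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class AblationSpec:
    """Inhibit attention to each in-context study example with prob ``p_a``."""

    p_a: float
    mode: str = "drop"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError(f"p_a must be in [0, 1], got {self.p_a}")
        if self.mode == "noise":
            raise NotImplementedError(
                "the additive-noise attention variant is a config hook only"
            )
        if self.mode != "drop":
            raise ValueError(f"unknown ablation mode {self.mode!r}")


def param_count(config: ModelConfig) -> int:
    """Closed-form learnable-parameter count for :class:`ModelConfig`."""
    d, f, v = config.hidden_size, config.ffn_size, config.d_v
    per_layer = (
        4 * (d * d + d)      # q, k, v, o projections
        + (d * f + f) + (f * d + d)  # feedforward
        + 4 * d              # two layer norms
    )
    return (
        v * d                       # token embeddings
        + config.max_sequence_length * d  # positional embeddings
        + config.n_layers * per_layer
        + 2 * d                     # final layer norm
        + d * v + v                 # output projection
    )


class ModelState:
    """Architecture configuration plus learnable parameters."""

    def __init__(self, config: ModelConfig, params: dict[str, np.ndarray]):
        self.config = config
        self.params = params

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy(self) -> "ModelState":
        return ModelState(self.config, {k: v.copy() for k, v in self.params.items()})

    def params_fingerprint(self) -> bytes:
        import hashlib

        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.digest()


def _sinusoid(n: int, d: int) -> np.ndarray:
    pe = np.zeros((n, d), dtype=np.float32)
    pos = np.arange(n)[:, None]
    div = np.exp(np.arange(0, d, 2) * (-np.log(10000.0) / d))
    pe[:, 0::2] = np.sin(pos * div)
    pe[:, 1::2] = np.cos(pos * div)
    return pe


def init_model(config: ModelConfig) -> ModelState:
    """Initialize embeddings and transformer parameters from ``config.seed``.

    Positional embeddings start from a (scaled) sinusoid and the q/k
    projections from a scaled identity by default: content-based matching
    between identical tokens is then available from the first step, which
    substantially shortens the optimization path to in-context retrieval.
    Both remain fully learnable.
    """
    rng = np.random.default_rng(config.seed)
    d, f, v = config.hidden_size, config.ffn_size, config.d_v
    scale = 0.02

    def w(*shape):
        return (rng.standard_normal(shape) * scale).astype(np.float32)

    e = config.emb_init_scale
    if config.pos_init == "sinusoid":
        pos_emb = config.pos_init_scale * _sinusoid(config.max_sequence_length, d)
    elif config.pos_init == "random":
        pos_emb = (rng.standard_normal((config.max_sequence_length, d))
                   * config.pos_init_scale).astype(np.float32)
    else:
        raise ValueError(f"unknown pos_init {config.pos_init!r}")
    params: dict[str, np.ndarray] = {
        "tok_emb": (rng.standard_normal((v, d)) * e).astype(np.float32),
        "pos_emb": pos_emb,
        "lnf_g": np.ones(d, dtype=np.float32),
        "lnf_b": np.zeros(d, dtype=np.float32),
        "w_out": w(d, v),
        "b_out": np.zeros(v, dtype=np.float32),
    }
    for layer in range(config.n_layers):
        p = f"l{layer}_"
        params[p + "ln1_g"] = np.ones(d, dtype=np.float32)
        params[p + "ln1_b"] = np.zeros(d, dtype=np.float32)
        params[p + "ln2_g"] = np.ones(d, dtype=np.float32)
        params[p + "ln2_b"] = np.zeros(d, dtype=np.float32)
        for name in ("wq", "wk", "wv", "wo"):
            if name in ("wq", "wk") and config.qk_init == "identity":
                params[p + name] = (0.5 * np.eye(d)).astype(np.float32)
            else:
                params[p + name] = w(d, d)
            params[p + name.replace("w", "b")] = np.zeros(d, dtype=np.float32)
        params[p + "w1"] = w(d, f)
        params[p + "b1"] = np.zeros(f, dtype=np.float32)
        params[p + "w2"] = w(f, d)
        params[p + "b2"] = np.zeros(d, dtype=np.float32)
    if config.circuit_init:
        if config.pos_encoding != "rope":
            raise ValueError("circuit_init requires pos_encoding='rope'")
        _apply_circuit_init(config, params)
    return ModelState(config, params)


def _apply_circuit_init(config: ModelConfig, params: dict) -> None:
    """Warm-start the two-hop retrieval circuit in layer 0.

    The first few heads of layer 0 are initialized as fixed-offset
    previous-token heads: with rotary encodings, attention from position i
    to j depends on q.R(j-i).k, so zeroing the head's q/k projections and
    setting rotated biases makes the head attend to offset -o at
    initialization.  Layer 0's value/output paths start as scaled
    identities so the attended content actually enters the residual
    stream.  Everything remains learnable.
    """
    d = config.hidden_size
    dh = d // config.n_heads
    half = dh // 2
    inv_freq = 10000.0 ** (-np.arange(half) / half)
    c = 2.0  # peak attention score c^2 * (dh/2) / sqrt(dh) over the offset
    n_offset_heads = min(3, config.n_heads - 1)
    wq = params["l0_wq"]
    wk = params["l0_wk"]
    bq = params["l0_bq"]
    bk = params["l0_bk"]
    for h in range(n_offset_heads):
        offset = h + 1
        sl = slice(h * dh, (h + 1) * dh)
        wq[:, sl] = 0.0
        wk[:, sl] = 0.0
        pair_q = np.zeros(dh, dtype=np.float32)
        pair_k = np.zeros(dh, dtype=np.float32)
        pair_q[0::2] = c
        pair_k[0::2] = c * np.cos(offset * inv_freq)
        pair_k[1::2] = c * np.sin(offset * inv_freq)
        bq[sl] = pair_q
        bk[sl] = pair_k
    # identity value/output paths so attended content reaches the residual
    # stream (and ultimately the logits) from the first step
    for layer in range(config.n_layers):
        params[f"l{layer}_wv"] = (0.5 * np.eye(d)).astype(np.float32)
        params[f"l{layer}_wo"] = (0.5 * np.eye(d)).astype(np.float32)


# ---------------------------------------------------------------------------
# batching


@dataclass
class Batch:
    """Homogeneous batch of episodes laid out for teacher forcing.

    ``ids``/``positions`` are the model inputs (context + query + all but
    the last answer token); the model is supervised at ``loss_idx`` to
    produce ``targets``.  ``key_visible`` marks which positions may serve
    as attention keys (False = ablated study example).
    """

    ids: np.ndarray          # (B, T) int64
    positions: np.ndarray    # (B, T) int64
    key_visible: np.ndarray  # (B, T) bool
    loss_idx: np.ndarray     # (B, K) int64
    targets: np.ndarray      # (B, K) int64
    target_weights: np.ndarray | None = None  # (K,) float32, None = uniform
    episodes: list[Episode] = field(default_factory=list)


def make_batch(
    episodes: Sequence[Episode],
    ablation: AblationSpec | None = None,
    rng: np.random.Generator | None = None,
    context_supervision: bool = False,
    query_loss_share: float = 0.5,
) -> Batch:
    """Stack same-length episodes; optionally sample an attention ablation.

    The ablation is sampled once per episode: each study example is dropped
    independently with probability ``p_a`` and its token span is then
    invisible to attention at every layer and head.

    With ``context_supervision`` the batch is additionally supervised on the
    answer tokens of every in-context study example (used during
    metalearning to shape the in-context algorithm); the query's answer
    positions always come last.
    """
    lens = {len(e.tokens) for e in episodes}
    klens = {len(e.target) for e in episodes}
    if len(lens) != 1 or len(klens) != 1:
        raise ValueError("episodes in a batch must share token/target lengths")
    n_ctx = lens.pop()
    k = klens.pop()
    t = n_ctx + k - 1
    b = len(episodes)
    ids = np.empty((b, t), dtype=np.int64)
    pos = np.empty((b, t), dtype=np.int64)
    key_visible = np.ones((b, t), dtype=bool)
    for i, e in enumerate(episodes):
        ids[i, :n_ctx] = e.tokens
        pos[i, :n_ctx] = e.positions
        if k > 1:
            ids[i, n_ctx:] = e.target[:-1]
            pos[i, n_ctx:] = e.target_positions[:-1]
        if ablation is not None and ablation.p_a > 0 and e.example_spans:
            if rng is None:
                raise ValueError("ablation sampling requires an rng")
            drop = rng.random(len(e.example_spans)) < ablation.p_a
            for (s, eidx), d in zip(e.example_spans, drop):
                if d:
                    key_visible[i, s:eidx] = False
    answer_idx = np.arange(n_ctx - 1, n_ctx - 1 + k)
    if context_supervision:
        ctx_idx: list[int] = []
        ctx_tgt_rows = []
        e0 = episodes[0]
        for s, eidx in e0.example_spans:
            # the last k tokens of each study example are its answer tokens
            ctx_idx.extend(range(eidx - 1 - k, eidx - 1))
        ctx_idx_arr = np.array(ctx_idx, dtype=np.int64)
        for e in episodes:
            ctx_tgt_rows.append(e.tokens[ctx_idx_arr + 1])
        loss_idx = np.tile(np.concatenate([ctx_idx_arr, answer_idx]), (b, 1))
        targets = np.concatenate(
            [np.stack(ctx_tgt_rows), np.stack([e.target for e in episodes])],
            axis=1,
        )
        # the query answer carries ``query_loss_share`` of the loss mass
        if not 0.0 < query_loss_share < 1.0:
            raise ValueError("query_loss_share must be in (0, 1)")
        weights = np.ones(loss_idx.shape[1], dtype=np.float32)
        share = query_loss_share / (1.0 - query_loss_share)
        weights[-k:] = share * len(ctx_idx_arr) / k
        return Batch(ids=ids, positions=pos, key_visible=key_visible,
                     loss_idx=loss_idx, targets=targets,
                     target_weights=weights, episodes=list(episodes))
    loss_idx = np.tile(answer_idx, (b, 1))
    targets = np.stack([e.target for e in episodes])
    return Batch(ids=ids, positions=pos, key_visible=key_visible,
                 loss_idx=loss_idx, targets=targets, episodes=list(episodes))


# ---------------------------------------------------------------------------
# primitive ops


def _ln_fwd(x, g, b):
    return K.ln_fwd(x, g, b, LN_EPS)

def _ln_bwd(dout, g, cache):
    return K.ln_bwd(dout, g, cache)


def _split_heads(x, n_heads):
    b, t, d = x.shape
    return x.reshape(b, t, n_heads, d // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x):
    b, h, t, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, t, h * dh)


def _rope_tables(positions: np.ndarray, dh: int):
    """Rotary-embedding cos/sin tables, shape (B, T, dh/2)."""
    half = dh // 2
    inv_freq = (10000.0 ** (-np.arange(half) / half)).astype(np.float32)
    ang = positions[:, :, None].astype(np.float32) * inv_freq
    return np.ascontiguousarray(np.cos(ang)), np.ascontiguousarray(np.sin(ang))


def _rope_apply(x, rope, inverse=False):
    """Rotate a fresh contiguous (B,H,T,dh) array in place."""
    cos, sin = rope
    return K.rope_apply_(np.ascontiguousarray(x), cos, sin, inverse=inverse)


def _layer_fwd(x, lp, mask_add, n_heads, drops, rope=None):
    """One pre-LN transformer layer.  Returns (x_out, internals)."""
    h1, ln1c = _ln_fwd(x, lp["ln1_g"], lp["ln1_b"])
    q = _split_heads(h1 @ lp["wq"] + lp["bq"], n_heads)
    kk = _split_heads(h1 @ lp["wk"] + lp["bk"], n_heads)
    v = np.ascontiguousarray(_split_heads(h1 @ lp["wv"] + lp["bv"], n_heads))
    if rope is not None:
        q = _rope_apply(q, rope)
        kk = _rope_apply(kk, rope)
    else:
        q = np.ascontiguousarray(q)
        kk = np.ascontiguousarray(kk)
    scale = np.float32(1.0 / np.sqrt(q.shape[-1]))
    s = q @ kk.transpose(0, 1, 3, 2)
    s *= scale
    p = K.attn_softmax(s, mask_add)  # in place: causal + key visibility
    a = _merge_heads(p @ v)
    attn_out = a @ lp["wo"] + lp["bo"]
    if drops is not None:
        attn_out = attn_out * drops[0]
    x1 = x + attn_out
    h2, ln2c = _ln_fwd(x1, lp["ln2_g"], lp["ln2_b"])
    u = h2 @ lp["w1"] + lp["b1"]
    relu = np.maximum(u, 0.0)
    ff = relu @ lp["w2"] + lp["b2"]
    if drops is not None:
        ff = ff * drops[1]
    x_out = x1 + ff
    internals = (h1, ln1c, q, kk, v, p, a, x1, h2, ln2c, relu, scale)
    return x_out, internals


def _layer_bwd(dx_out, x, lp, mask_add, n_heads, drops, internals, rope=None):
    """Gradients of one layer w.r.t. its input and parameters."""
    h1, ln1c, q, kk, v, p, a, x1, h2, ln2c, relu, scale = internals
    grads = {}
    b, t, d = x.shape

    dff = dx_out if drops is None else dx_out * drops[1]
    flat_relu = relu.reshape(-1, relu.shape[-1])
    grads["w2"] = flat_relu.T @ dff.reshape(-1, d)
    grads["b2"] = dff.sum((0, 1))
    drelu = dff @ lp["w2"].T
    du = drelu * (relu > 0)
    grads["w1"] = h2.reshape(-1, d).T @ du.reshape(-1, du.shape[-1])
    grads["b1"] = du.sum((0, 1))
    dh2 = du @ lp["w1"].T
    dx1_ln, grads["ln2_g"], grads["ln2_b"] = _ln_bwd(dh2, lp["ln2_g"], ln2c)
    dx1 = dx_out + dx1_ln

    dattn_out = dx1 if drops is None else dx1 * drops[0]
    grads["wo"] = a.reshape(-1, d).T @ dattn_out.reshape(-1, d)
    grads["bo"] = dattn_out.sum((0, 1))
    da = np.ascontiguousarray(_split_heads(dattn_out @ lp["wo"].T, n_heads))
    dp = da @ v.transpose(0, 1, 3, 2)
    dv = p.transpose(0, 1, 3, 2) @ da
    ds = K.softmax_bwd(p, dp)  # overwrites dp; masked entries have p == 0
    dq = ds @ kk * scale
    dk = ds.transpose(0, 1, 3, 2) @ q * scale
    if rope is not None:  # q/k were rotated after the linear projection
        dq = _rope_apply(dq, rope, inverse=True)
        dk = _rope_apply(dk, rope, inverse=True)
    dq, dk, dv = (_merge_heads(z) for z in (dq, dk, dv))
    h1_flat = h1.reshape(-1, d)
    dh1 = np.zeros_like(h1)
    for name, dz in (("wq", dq), ("wk", dk), ("wv", dv)):
        grads[name] = h1_flat.T @ dz.reshape(-1, d)
        grads[name.replace("w", "b")] = dz.sum((0, 1))
        dh1 += dz @ lp[name].T
    dx_ln, grads["ln1_g"], grads["ln1_b"] = _ln_bwd(dh1, lp["ln1_g"], ln1c)
    dx = dx1 + dx_ln
    return dx.astype(np.float32), grads


def _layer_params(params, layer):
    p = f"l{layer}_"
    return {k[len(p):]: v for k, v in params.items() if k.startswith(p)}


# ---------------------------------------------------------------------------
# forward / loss / backward


def _embed(state: ModelState, batch: Batch):
    x = state.params["tok_emb"][batch.ids]
    if state.config.pos_encoding == "learned":
        x = x + state.params["pos_emb"][batch.positions]
    return x.astype(np.float32)


def _check_batch(state: ModelState, batch: Batch) -> None:
    t = batch.ids.shape[1]
    max_pos = int(batch.positions.max())
    if max_pos >= state.config.max_sequence_length:
        raise ValueError(
            f"sequence position {max_pos} exceeds max_sequence_length "
            f"{state.config.max_sequence_length}"
        )
    if t > state.config.max_sequence_length:
        raise ValueError("sequence longer than max_sequence_length")


def _forward_hidden(state: ModelState, batch: Batch, train: bool,
                    drop_rng: np.random.Generator | None,
                    keep_internals: bool = False):
    """Run the stack; returns final hidden states, per-layer inputs, masks.

    With ``keep_internals`` each layer's attention/FFN intermediates are
    cached for the backward pass (memory for compute); otherwise they are
    recomputed layer by layer during backprop.
    """
    cfg = state.config
    _check_batch(state, batch)
    mask_add = K.build_additive_mask(batch.key_visible)
    rope = None
    if cfg.pos_encoding == "rope":
        rope = _rope_tables(batch.positions, cfg.hidden_size // cfg.n_heads)
    elif cfg.pos_encoding != "learned":
        raise ValueError(f"unknown pos_encoding {cfg.pos_encoding!r}")
    x = _embed(state, batch)
    rate = cfg.dropout if train else 0.0
    drop_masks: list[tuple[np.ndarray, np.ndarray] | None] = []
    internals: list = []
    emb_mask = None
    if rate > 0.0:
        if drop_rng is None:
            raise ValueError("training with dropout requires drop_rng")
        keep = 1.0 - rate

        def dmask():
            return (drop_rng.random(x.shape) < keep).astype(np.float32) / keep

        emb_mask = dmask()
        x = x * emb_mask
    xs = [x]
    for layer in range(cfg.n_layers):
        drops = None
        if rate > 0.0:
            drops = (dmask(), dmask())
        drop_masks.append(drops)
        x, layer_internals = _layer_fwd(x, _layer_params(state.params, layer),
                                        mask_add, cfg.n_heads, drops,
                                        rope=rope)
        internals.append(layer_internals if keep_internals else None)
        xs.append(x)
    return xs, mask_add, drop_masks, emb_mask, internals, rope


def _gather(h, idx):
    b = h.shape[0]
    return h[np.arange(b)[:, None], idx]


def _softmax(z):
    z = z - z.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


def forward(
    state: ModelState,
    episodes: Sequence[Episode] | Episode,
    ablation: AblationSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-position next-token distributions, shape (B, T, d_v).

    Evaluation-mode (no dropout); parameters are left untouched.
    """
    if isinstance(episodes, Episode):
        episodes = [episodes]
    batch = make_batch(episodes, ablation=ablation, rng=rng)
    xs, *_ = _forward_hidden(state, batch, train=False, drop_rng=None)
    h, _ = _ln_fwd(xs[-1], state.params["lnf_g"], state.params["lnf_b"])
    logits = h @ state.params["w_out"] + state.params["b_out"]
    return _softmax(logits)


def loss_and_grads(
    state: ModelState,
    batch: Batch,
    train: bool = True,
    drop_rng: np.random.Generator | None = None,
):
    """Mean cross-entropy at the answer positions and parameter gradients."""
    cfg = state.config
    params = state.params
    xs, mask_add, drop_masks, emb_mask, internals, rope = _forward_hidden(
        state, batch, train, drop_rng, keep_internals=True)
    h_sel = _gather(xs[-1], batch.loss_idx)  # (B, K, D)
    hn, lnfc = _ln_fwd(h_sel, params["lnf_g"], params["lnf_b"])
    logits = hn @ params["w_out"] + params["b_out"]  # (B, K, V)
    b, k, v = logits.shape
    loss, dlogits, _ = K.softmax_xent(
        np.ascontiguousarray(logits), batch.targets, batch.target_weights)

    grads: dict[str, np.ndarray] = {}
    d = cfg.hidden_size
    grads["w_out"] = hn.reshape(-1, d).T @ dlogits.reshape(-1, v)
    grads["b_out"] = dlogits.sum((0, 1))
    dhn = dlogits @ params["w_out"].T
    dh_sel, grads["lnf_g"], grads["lnf_b"] = _ln_bwd(dhn, params["lnf_g"], lnfc)

    dx = np.zeros_like(xs[-1])
    np.add.at(dx, (np.arange(b)[:, None], batch.loss_idx), dh_sel)

    for layer in reversed(range(cfg.n_layers)):
        lp = _layer_params(params, layer)
        cached = internals[layer]
        if cached is None:  # recompute (memory-for-compute tradeoff)
            _, cached = _layer_fwd(xs[layer], lp, mask_add, cfg.n_heads,
                                   drop_masks[layer], rope=rope)
        dx, lgrads = _layer_bwd(dx, xs[layer], lp, mask_add, cfg.n_heads,
                                drop_masks[layer], cached, rope=rope)
        internals[layer] = None  # free as we go
        for name, g in lgrads.items():
            grads[f"l{layer}_{name}"] = g

    if emb_mask is not None:
        dx = dx * emb_mask
    grads["tok_emb"] = np.zeros_like(params["tok_emb"])
    np.add.at(grads["tok_emb"], batch.ids.ravel(),
              dx.reshape(-1, d))
    if cfg.pos_encoding == "learned":
        grads["pos_emb"] = np.zeros_like(params["pos_emb"])
        np.add.at(grads["pos_emb"], batch.positions.ravel(),
                  dx.reshape(-1, d))
    for key in grads:
        grads[key] = grads[key].astype(np.float32)
    return loss, grads


def evaluate_loss(state: ModelState, batch: Batch) -> float:
    """Teacher-forced mean cross-entropy without gradients (eval mode)."""
    xs, *_ = _forward_hidden(state, batch, train=False, drop_rng=None)
    hn, _ = _ln_fwd(_gather(xs[-1], batch.loss_idx),
                    state.params["lnf_g"], state.params["lnf_b"])
    probs = _softmax(hn @ state.params["w_out"] + state.params["b_out"])
    b, k, _ = probs.shape
    picked = probs[np.arange(b)[:, None], np.arange(k)[None, :], batch.targets]
    return float(-np.log(np.maximum(picked, 1e-12)).mean())


def teacher_forced_predictions(state: ModelState, batch: Batch) -> np.ndarray:
    """Argmax tokens at the answer positions under teacher forcing, (B, K)."""
    xs, *_ = _forward_hidden(state, batch, train=False, drop_rng=None)
    hn, _ = _ln_fwd(_gather(xs[-1], batch.loss_idx),
                    state.params["lnf_g"], state.params["lnf_b"])
    logits = hn @ state.params["w_out"] + state.params["b_out"]
    return logits.argmax(-1)


def greedy_decode(
    state: ModelState,
    episodes: Sequence[Episode] | Episode,
    ablation: AblationSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Autoregressive argmax decoding of the answer tokens, shape (B, K).

    Deterministic given ``state`` and the (optional) ablation sample; the
    parameters are never modified.
    """
    single = isinstance(episodes, Episode)
    if single:
        episodes = [episodes]
    base = make_batch(episodes, ablation=ablation, rng=rng)
    k = base.targets.shape[1]
    n_ctx = base.ids.shape[1] - (k - 1)
    b = base.ids.shape[0]
    preds = np.zeros((b, k), dtype=np.int64)
    for step in range(k):
        t = n_ctx + step
        ids = base.ids[:, :t].copy()
        if step > 0:
            ids[:, n_ctx:] = preds[:, :step]
        sub = Batch(
            ids=ids,
            positions=base.positions[:, :t],
            key_visible=base.key_visible[:, :t],
            loss_idx=np.full((b, 1), t - 1, dtype=np.int64),
            targets=np.zeros((b, 1), dtype=np.int64),
        )
        xs, *_ = _forward_hidden(state, sub, train=False, drop_rng=None)
        hn, _ = _ln_fwd(_gather(xs[-1], sub.loss_idx),
                        state.params["lnf_g"], state.params["lnf_b"])
        logits = hn @ state.params["w_out"] + state.params["b_out"]
        preds[:, step] = logits[:, 0].argmax(-1)
    return preds[0] if single else preds


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with bias correction; state keyed by parameter name."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p) for k, p in params.items()}
        self.v = {k: np.zeros_like(p) for k, p in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: ModelState, path) -> None:
    """Write parameters (npz) with a JSON config sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state.params)
    path.with_suffix(".json").write_text(json.dumps(state.config.to_dict()))


def load_checkpoint(path) -> ModelState:
    path = Path(path)
    config = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k].copy() for k in data.files}
    return ModelState(config, params)


def save_text_checkpoint(state: ModelState, path) -> None:
    """Single-file text-portable checkpoint (JSON with base64 float32)."""
    import base64

    payload = {
        "config": state.config.to_dict(),
        "params": {
            k: {
                "shape": list(v.shape),
                "data": base64.b64encode(
                    np.ascontiguousarray(v, dtype=np.float32).tobytes()
                ).decode("ascii"),
            }
            for k, v in state.params.items()
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_text_checkpoint(path) -> ModelState:
    import base64

    payload = json.loads(Path(path).read_text())
    config = ModelConfig(**payload["config"])
    params = {
        k: np.frombuffer(base64.b64decode(v["data"]), dtype=np.float32)
        .reshape(v["shape"]).copy()
        for k, v in payload["params"].items()
    }
    return ModelState(config, params)
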