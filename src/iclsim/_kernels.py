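"""Fused numerical kernels for the transformer hot path.

Numba-jitted single-threaded kernels (used when numba is importable) with
pure-NumPy fallbacks.  Matrix products stay in BLAS; these kernels fuse the
memory-bound elementwise stages: masked causal softmax, layer norm, rotary
rotation, and the softmax/cross-entropy head.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

_JIT = dict(cache=True, fastmath=True)


# ---------------------------------------------------------------------------
# masked causal softmax over attention scores, in place





def build_additive_mask(key_visible):
    """(B,1,T,T) float32 additive mask: 0 allowed, -1e9 blocked."""
    b, t = key_visible.shape
    causal = np.tril(np.ones((t, t), dtype=bool))
    allowed = causal[None, :, :] & (
        key_visible[:, None, :] | np.eye(t, dtype=bool)[None, :, :])
    mask = np.where(allowed, np.float32(0.0), np.float32(-1e9))
    return mask[:, None, :, :]


def attn_softmax(s, mask_add):
    """In-place masked softmax using NumPy's SIMD exp (faster here than a
    scalar-exp jitted loop)."""
    s += mask_add
    s -= s.max(-1, keepdims=True)
    np.exp(s, out=s)
    s /= s.sum(-1, keepdims=True)
    return s


# ---------------------------------------------------------------------------
# softmax backward (rows are probability vectors): ds = p * (dp - <dp, p>)





def softmax_bwd(p, dp):
    """Overwrites dp with ds; returns dp."""
    dot = np.einsum("bhij,bhij->bhi", dp, p)[..., None]
    np.subtract(dp, dot, out=dp)
    np.multiply(dp, p, out=dp)
    return dp


# ---------------------------------------------------------------------------
# layer norm


@njit(**_JIT)
def _ln_fwd_(x2, g, b, out, xhat, inv, eps):
    n, d = x2.shape
    for i in range(n):
        mu = np.float32(0.0)
        for j in range(d):
            mu += x2[i, j]
        mu /= d
        var = np.float32(0.0)
        for j in range(d):
            diff = x2[i, j] - mu
            var += diff * diff
        var /= d
        iv = np.float32(1.0) / np.sqrt(var + eps)
        inv[i] = iv
        for j in range(d):
            xh = (x2[i, j] - mu) * iv
            xhat[i, j] = xh
            out[i, j] = xh * g[j] + b[j]


@njit(**_JIT)
def _ln_bwd_(dout2, g, xhat, inv, dx, dg, db):
    n, d = dout2.shape
    for i in range(n):
        m1 = np.float32(0.0)
        m2 = np.float32(0.0)
        for j in range(d):
            dxh = dout2[i, j] * g[j]
            m1 += dxh
            m2 += dxh * xhat[i, j]
        m1 /= d
        m2 /= d
        iv = inv[i]
        for j in range(d):
            dxh = dout2[i, j] * g[j]
            dx[i, j] = iv * (dxh - m1 - xhat[i, j] * m2)
            dg[j] += dout2[i, j] * xhat[i, j]
            db[j] += dout2[i, j]


def ln_fwd(x, g, b, eps=1e-5):
    shp = x.shape
    dt = x.dtype if x.dtype in (np.float32, np.float64) else np.float32
    x2 = np.ascontiguousarray(x, dtype=dt).reshape(-1, shp[-1])
    out = np.empty_like(x2)
    xhat = np.empty_like(x2)
    inv = np.empty(x2.shape[0], dtype=dt)
    if HAVE_NUMBA:
        _ln_fwd_(x2, g.astype(dt), b.astype(dt), out, xhat, inv, dt.type(eps))
    else:
        mu = x2.mean(-1, keepdims=True)
        xc = x2 - mu
        var = (xc * xc).mean(-1, keepdims=True)
        inv[:] = (1.0 / np.sqrt(var + eps))[:, 0]
        xhat[:] = xc * inv[:, None]
        out[:] = xhat * g + b
    return out.reshape(shp), (xhat, inv, shp)


def ln_bwd(dout, g, cache):
    xhat, inv, shp = cache
    dt = xhat.dtype
    dout2 = np.ascontiguousarray(dout, dtype=dt).reshape(-1, shp[-1])
    dx = np.empty_like(dout2)
    dg = np.zeros(shp[-1], dtype=dt)
    db = np.zeros(shp[-1], dtype=dt)
    if HAVE_NUMBA:
        _ln_bwd_(dout2, g.astype(dt), xhat, inv, dx, dg, db)
    else:
        dxh = dout2 * g
        m1 = dxh.mean(-1, keepdims=True)
        m2 = (dxh * xhat).mean(-1, keepdims=True)
        dx[:] = inv[:, None] * (dxh - m1 - xhat * m2)
        dg[:] = (dout2 * xhat).sum(0)
        db[:] = dout2.sum(0)
    return dx.reshape(shp), dg, db


# ---------------------------------------------------------------------------
# rotary rotation, in place


@njit(**_JIT)
def _rope_(x, cos, sin, sign):
    b_n, h_n, t_n, dh = x.shape
    half = dh // 2
    for b in range(b_n):
        for h in range(h_n):
            for t in range(t_n):
                for p in range(half):
                    c = cos[b, t, p]
                    s = sign * sin[b, t, p]
                    x1 = x[b, h, t, 2 * p]
                    x2 = x[b, h, t, 2 * p + 1]
                    x[b, h, t, 2 * p] = x1 * c - x2 * s
                    x[b, h, t, 2 * p + 1] = x1 * s + x2 * c


def rope_apply_(x, cos, sin, inverse=False):
    """Rotate (B,H,T,dh) in place; cos/sin are (B,T,dh/2)."""
    sign = np.float32(-1.0 if inverse else 1.0)
    if HAVE_NUMBA:
        _rope_(x, cos, sin, sign)
        return x
    c = cos[:, None, :, :]
    s = (sin if not inverse else -sin)[:, None, :, :]
    x1 = x[..., 0::2].copy()
    x2 = x[..., 1::2].copy()
    x[..., 0::2] = x1 * c - x2 * s
    x[..., 1::2] = x1 * s + x2 * c
    return x


# ---------------------------------------------------------------------------
# softmax cross-entropy head





def softmax_xent(logits, targets, weights=None):
    """Returns (loss, dlogits, picked_probs); ``weights`` (K,) sum-normalized
    across the batch like a weighted mean."""
    b, k, v = logits.shape
    dt = logits.dtype
    if weights is None:
        w = np.full(k, 1.0 / (b * k), dtype=dt)
    else:
        w = (weights / (b * weights.sum())).astype(dt)
    dlogits = np.empty_like(logits)
    picked = np.empty((b, k), dtype=dt)
    m = logits.max(-1, keepdims=True)
    e = np.exp(logits - m)
    z = e.sum(-1, keepdims=True)
    probs = e / z
    rows = np.arange(b)[:, None], np.arange(k)[None, :]
    picked[:] = probs[rows[0], rows[1], targets]
    loss = float((-np.log(np.maximum(picked, 1e-12)) * w).sum())
    dlogits[:] = probs * w[None, :, None]
    dlogits[rows[0], rows[1], targets] -= w[None, :]
    return loss, dlogits, picked


def warmup_kernels():
    """Trigger JIT compilation on tiny inputs (avoids first-step stalls)."""
    if not HAVE_NUMBA:
        return
    x = np.zeros((1, 4), dtype=np.float32)
    g = np.ones(4, dtype=np.float32)
    out, cache = ln_fwd(x, g, np.zeros(4, dtype=np.float32))
    ln_bwd(out, g, cache)
    r = np.zeros((1, 1, 2, 4), dtype=np.float32)
    cs = np.ones((1, 2, 2), dtype=np.float32)
    rope_apply_(r, cs, cs)
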