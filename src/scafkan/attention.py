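"""Multi-head scaled dot-product cross-attention.

One representation supplies the queries, the other the keys and values;
per query token the attention weights are a softmax over key tokens, so
they are non-negative and sum to one.  The attended context passes through
an output projection and is added residually to the query source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Linear, Module, Tensor

__all__ = ["MultiheadCrossAttention", "AttentionDetails", "cross_attention"]


@dataclass
class AttentionDetails:
    """Intermediate quantities of one attention pass (for diagnostics)."""

    weights: np.ndarray      # (n, H, Tq, Tk), rows sum to 1 over Tk
    context: np.ndarray      # (n, Tq, d) attended values, pre output projection
    pre_residual: np.ndarray  # (n, Tq, d) after output projection, before residual


class MultiheadCrossAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads != 0:
            raise ValueError(f"token dimension {d} not divisible by {n_heads} heads")
        self.d = d
        self.n_heads = n_heads
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.last_details: AttentionDetails | None = None

    def forward(self, q_src: Tensor, kv_src: Tensor,
                keep_details: bool = False) -> Tensor:
        n, tq, d = q_src.shape
        tk = kv_src.shape[1]
        if kv_src.shape[-1] != d or kv_src.shape[0] != n:
            raise ValueError("query and key/value sources must share n and d")
        h, dh = self.n_heads, d // self.n_heads

        def split(x: Tensor, t: int) -> Tensor:
            return x.reshape(n, t, h, dh).transpose(0, 2, 1, 3)   # (n, H, T, dh)

        q = split(self.wq(q_src), tq)
        k = split(self.wk(kv_src), tk)
        v = split(self.wv(kv_src), tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)     # (n, H, Tq, Tk)
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, tq, d)
        projected = self.wo(ctx)
        if keep_details:
            self.last_details = AttentionDetails(
                weights=attn.data.copy(), context=ctx.data.copy(),
                pre_residual=projected.data.copy())
        return q_src + projected


def cross_attention(attn: MultiheadCrossAttention, q_src: np.ndarray,
                    kv_src: np.ndarray) -> tuple[np.ndarray, AttentionDetails]:
    """Functional wrapper over (n, d) or (n, T, d) arrays; returns details."""
    q = np.asarray(q_src, float)
    kv = np.asarray(kv_src, float)
    if q.ndim == 2:
        q = q[:, None, :]
    if kv.ndim == 2:
        kv = kv[:, None, :]
    out = attn(Tensor(q), Tensor(kv), keep_details=True)
    return out.data, attn.last_details
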