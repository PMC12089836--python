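"""Multiscale multihead self-attention (M2SA) and the top-level encoder layer.

The encoder layer (AIFI: attention-based intra-scale feature interaction)
runs on the stride-32 map only.  The baseline flavour uses plain multi-head
self-attention; the M2SA flavour fuses three branches:

* a multi-scale gating branch — 1x1 reduction to C/4, parallel depthwise
  3x3 atrous convolutions at rates {1, 3, 5}, summed, restored to C, and
  used as a multiplicative gate on the input;
* an attention branch — queries from the raw feature, keys/values from the
  multi-scale-gated feature, scaled dot-product attention over all spatial
  tokens;
* a squeeze-excitation channel-attention branch.

The three branch outputs are summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nnkit as nn
from .errors import ConfigError, NumericalError
from .nnkit import Tensor
from .nnkit.tensor import add_flops


# ---------------------------------------------------------------------------
# shared attention machinery
# ---------------------------------------------------------------------------

def build_2d_sincos_pos_embed(h, w, dim, temperature=10000.0):
    """Deterministic 2-D sine-cosine positional embedding, (h*w, dim)."""
    if dim % 4:
        raise ConfigError("positional embedding dim must be divisible by 4")
    gw, gh = np.meshgrid(np.arange(w, dtype=np.float64),
                         np.arange(h, dtype=np.float64))
    pos_dim = dim // 4
    omega = 1.0 / temperature ** (np.arange(pos_dim, dtype=np.float64) / pos_dim)
    out_w = gw.reshape(-1)[:, None] * omega[None]
    out_h = gh.reshape(-1)[:, None] * omega[None]
    emb = np.concatenate([np.sin(out_w), np.cos(out_w),
                          np.sin(out_h), np.cos(out_h)], axis=1)
    return emb.astype(np.float32)


def scaled_dot_product(q, k, v, heads, mask=None, name="attention"):
    """Multi-head attention core over (N, L, C) token tensors.

    ``mask`` is an additive (L_q, L_k) float array (0 / -inf pattern).
    Counts the two token-mixing matmuls in meta mode through the matmul
    primitive itself.
    """
    n, lq, c = q.shape
    lk = k.shape[1]
    dk = c // heads

    def split(t, l):
        return t.reshape(n, l, heads, dk).transpose(0, 2, 1, 3)

    qh, kh, vh = split(q, lq), split(k, lk), split(v, lk)
    logits = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dk))
    if not logits.is_meta and not np.isfinite(logits.data).all():
        raise NumericalError(f"non-finite attention logits in {name}")
    if mask is not None:
        logits = logits + Tensor(mask[None, None])
    attn = nn.softmax(logits, axis=-1)
    out = attn @ vh
    return out.transpose(0, 2, 1, 3).reshape(n, lq, c), attn


class MultiHeadAttention(nn.Module):
    """Standard MHSA with separate q/k/v projections and output projection."""

    def __init__(self, dim, heads):
        super().__init__()
        if dim % heads:
            raise ConfigError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads = dim, heads
        self.wq = nn.Linear(dim, dim)
        self.wk = nn.Linear(dim, dim)
        self.wv = nn.Linear(dim, dim)
        self.proj = nn.Linear(dim, dim)

    def forward(self, q, k, v, mask=None):
        out, _ = scaled_dot_product(self.wq(q), self.wk(k), self.wv(v),
                                    self.heads, mask, name="mhsa")
        return self.proj(out)


# ---------------------------------------------------------------------------
# M2SA
# ---------------------------------------------------------------------------

@dataclass
class M2SAConfig:
    hidden: int = 256
    heads: int = 8
    dilations: tuple = (1, 3, 5)
    reduction: int = 4           # channel reduction of the multi-scale branch
    se_reduction: int = 16       # squeeze-excitation bottleneck ratio
    kv_downsample: int = 1       # extra pooling on K/V tokens
    literal_double_gate: bool = False

    def __post_init__(self):
        if self.hidden % self.heads:
            raise ConfigError("hidden width must be divisible by heads")
        if self.hidden % self.reduction:
            raise ConfigError("hidden width must be divisible by the "
                              "multi-scale reduction")
        if self.hidden % self.se_reduction:
            raise ConfigError("hidden width must be divisible by the SE reduction")


class MultiScaleBranch(nn.Module):
    """Eq-style gating: dilated depthwise pyramid -> 1x1 restore -> gate x."""

    def __init__(self, cfg: M2SAConfig):
        super().__init__()
        c, cr = cfg.hidden, cfg.hidden // cfg.reduction
        self.cfg = cfg
        self.reduce = nn.Conv2d(c, cr, 1)
        self.dilated = nn.ModuleList([
            nn.Conv2d(cr, cr, 3, dilation=d, groups=cr) for d in cfg.dilations])
        self.restore = nn.Conv2d(cr, c, 1)

    def gate(self, x):
        r = self.reduce(x)
        s = None
        for conv in self.dilated:
            s = conv(r) if s is None else s + conv(r)
        return self.restore(s)

    def forward(self, x):
        g = self.gate(x) * x
        if self.cfg.literal_double_gate:
            g = g * x
        return g


class ChannelAttention(nn.Module):
    """Squeeze-excitation: GAP -> 1x1 -> ReLU6 -> 1x1 -> sigmoid gate."""

    def __init__(self, cfg: M2SAConfig):
        super().__init__()
        c, cs = cfg.hidden, cfg.hidden // cfg.se_reduction
        self.squeeze = nn.Conv2d(c, cs, 1)
        self.excite = nn.Conv2d(cs, c, 1)

    def forward(self, x):
        p = nn.global_avg_pool(x)
        w = nn.sigmoid(self.excite(nn.relu6(self.squeeze(p))))
        return w * x


class M2SA(nn.Module):
    """The fused three-branch block, shape-preserving on (N, C, H, W)."""

    def __init__(self, cfg: M2SAConfig | None = None):
        super().__init__()
        self.cfg = cfg or M2SAConfig()
        c = self.cfg.hidden
        self.multiscale = MultiScaleBranch(self.cfg)
        self.channel = ChannelAttention(self.cfg)
        self.wq = nn.Linear(c, c)
        self.wk = nn.Linear(c, c)
        self.wv = nn.Linear(c, c)
        self.proj = nn.Linear(c, c)

    def attention_branch(self, x, x_msa, pos=None):
        n, c, h, w = x.shape
        q_src = x.reshape(n, c, h * w).transpose(0, 2, 1)
        kv_map = x_msa
        if self.cfg.kv_downsample > 1:
            kv_map = nn.avg_pool2d(kv_map, self.cfg.kv_downsample)
        hk, wk = kv_map.shape[2], kv_map.shape[3]
        kv_src = kv_map.reshape(n, c, hk * wk).transpose(0, 2, 1)
        if pos is not None:
            q_in = q_src + pos
            k_in = kv_src + pos if kv_src.shape[1] == pos.shape[-2] else kv_src
        else:
            q_in, k_in = q_src, kv_src
        out, _ = scaled_dot_product(self.wq(q_in), self.wk(k_in), self.wv(kv_src),
                                    self.cfg.heads, name="m2sa.attention")
        out = self.proj(out)
        return out.transpose(0, 2, 1).reshape(n, c, h, w)

    def forward(self, x, pos=None):
        x_msa = self.multiscale(x)
        att = self.attention_branch(x, x_msa, pos)
        x_ca = self.channel(x)
        for br, name in ((x_msa, "multiscale"), (att, "attention"), (x_ca, "channel")):
            assert br.shape == x.shape, f"{name} branch changed shape"
        return x_msa + att + x_ca


# ---------------------------------------------------------------------------
# AIFI encoder layer (baseline MHSA or M2SA flavour)
# ---------------------------------------------------------------------------

class AIFILayer(nn.Module):
    """Post-norm transformer encoder layer on the stride-32 map only."""

    def __init__(self, hidden=256, heads=8, ffn=1024, attn="mhsa",
                 m2sa_cfg: M2SAConfig | None = None, level="p5"):
        super().__init__()
        if str(level).lower() != "p5":
            raise ConfigError(
                f"AIFI is intra-scale on the top level only; got level={level!r}")
        self.hidden, self.attn_kind = hidden, attn
        if attn == "mhsa":
            self.attn = MultiHeadAttention(hidden, heads)
        elif attn == "m2sa":
            self.attn = M2SA(m2sa_cfg or M2SAConfig(hidden=hidden, heads=heads))
        else:
            raise ConfigError(f"unknown AIFI attention flavour {attn!r}")
        self.norm1 = nn.LayerNorm(hidden)
        self.norm2 = nn.LayerNorm(hidden)
        self.ffn1 = nn.Linear(hidden, ffn)
        self.ffn2 = nn.Linear(ffn, hidden)
        self._pos_cache = {}

    def pos_embed(self, h, w):
        key = (h, w)
        if key not in self._pos_cache:
            self._pos_cache[key] = build_2d_sincos_pos_embed(h, w, self.hidden)
        return self._pos_cache[key]

    def forward(self, x):
        n, c, h, w = x.shape
        pos = Tensor(self.pos_embed(h, w)[None])
        if self.attn_kind == "m2sa":
            att = self.attn(x, pos=pos)
            tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
            att = att.reshape(n, c, h * w).transpose(0, 2, 1)
        else:
            tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
            qk = tokens + pos
            att = self.attn(qk, qk, tokens)
        y = self.norm1(tokens + att)
        z = self.norm2(y + self.ffn2(nn.relu(self.ffn1(y))))
        return z.transpose(0, 2, 1).reshape(n, c, h, w)


def build_m2sa_aifi(cfg: M2SAConfig | None = None, hidden=256, heads=8,
                    ffn=1024) -> AIFILayer:
    """Encoder layer whose self-attention sublayer is the M2SA block."""
    cfg = cfg or M2SAConfig(hidden=hidden, heads=heads)
    return AIFILayer(hidden=cfg.hidden, heads=cfg.heads, ffn=ffn,
                     attn="m2sa", m2sa_cfg=cfg)
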