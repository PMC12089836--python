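"""Haar wavelet transforms and the wavelet-transform convolution (WTConv).

The 2-D orthonormal Haar transform splits a feature map into a low-frequency
approximation (LL) and three detail bands (LH, HL, HH), each at half the
spatial resolution.  WTConv exploits this: a small depthwise kernel applied
to subbands at level i has an effective receptive field of ``2**i * k`` in
the original resolution, so stacking a few decomposition levels buys a large
receptive field for very few parameters and FLOPs.

Subband orientation convention (fixed against a separable-filter oracle):
``LH`` holds the column-difference (responds to vertical edges), ``HL`` the
row-difference (horizontal edges), ``HH`` the diagonal difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit as nn
from .errors import ArgumentError, ConfigError
from .nnkit import Tensor
from .nnkit.tensor import add_flops, concat, ensure, reflect_pad2d


# ---------------------------------------------------------------------------
# Haar analysis / synthesis
# ---------------------------------------------------------------------------

def _pad_to_even(x):
    """Reflect-pad right/bottom so both spatial dims are even."""
    H, W = x.shape[-2], x.shape[-1]
    pb, pr = H % 2, W % 2
    if pb or pr:
        x = reflect_pad2d(x, (0, pb, 0, pr))
    return x, (H, W)


def haar_dwt2(x):
    """One level of the orthonormal 2-D Haar transform.

    Input (..., H, W) with H, W even (odd sizes are reflect-padded first).
    Returns (LL, LH, HL, HH), each (..., H/2, W/2).  Every output pixel is a
    +-1/2-weighted sum of one 2x2 input block, so the transform is
    orthonormal: energy is conserved and the inverse is the transpose.
    """
    x = ensure(x)
    if x.numel() == 0:
        raise ArgumentError("haar_dwt2: empty input map")
    x, _ = _pad_to_even(x)
    a = x[..., 0::2, 0::2]
    b = x[..., 0::2, 1::2]
    c = x[..., 1::2, 0::2]
    d = x[..., 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5   # column difference
    hl = (a + b - c - d) * 0.5   # row difference
    hh = (a - b - c + d) * 0.5   # diagonal difference
    return ll, lh, hl, hh


def haar_idwt2(subbands):
    """Exact inverse of :func:`haar_dwt2` (transpose of the analysis map)."""
    ll, lh, hl, hh = [ensure(s) for s in subbands]
    shapes = {s.shape for s in (ll, lh, hl, hh)}
    if len(shapes) != 1:
        raise ArgumentError(f"haar_idwt2: subband shape mismatch {sorted(shapes)}")
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    c = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5

    def interleave(p, q, axis):
        # stack along a new axis after `axis`, then fold it in
        shp = list(p.shape)
        shp.insert(axis + 1 if axis >= 0 else p.ndim + axis + 1, 1)
        p2 = p.reshape(shp)
        q2 = q.reshape(shp)
        cat = concat([p2, q2], axis=axis + 1 if axis >= 0 else p.ndim + axis + 1)
        out_shape = list(p.shape)
        ax = axis if axis >= 0 else p.ndim + axis
        out_shape[ax] = p.shape[ax] * 2
        return cat.reshape(out_shape)

    top = interleave(a, b, -1)      # rows 0,2,...  (interleave columns)
    bot = interleave(c, d, -1)      # rows 1,3,...
    return interleave(top, bot, -2)


@dataclass
class SubbandPyramid:
    """Multi-level Haar decomposition.

    ``details[i]`` holds (LH, HL, HH) of level i (spatial size H/2^(i+1));
    ``approx`` is the LL map remaining after the deepest level.
    """

    details: list = field(default_factory=list)
    approx: Tensor = None

    @property
    def levels(self):
        """Per-level (LL, LH, HL, HH) views; LL of level i is the map that
        was decomposed further for i+1 (the deepest LL is ``approx``)."""
        out = []
        for i, (lh, hl, hh) in enumerate(self.details):
            ll = self.approx if i == len(self.details) - 1 else None
            out.append((ll, lh, hl, hh))
        return out


def decompose(x, levels: int) -> SubbandPyramid:
    if levels < 1:
        raise ArgumentError("decompose: levels must be >= 1")
    pyr = SubbandPyramid()
    cur = ensure(x)
    for _ in range(levels):
        ll, lh, hl, hh = haar_dwt2(cur)
        pyr.details.append((lh, hl, hh))
        cur = ll
    pyr.approx = cur
    return pyr


def reconstruct(pyr: SubbandPyramid):
    cur = pyr.approx
    for lh, hl, hh in reversed(pyr.details):
        cur = haar_idwt2((cur, lh, hl, hh))
    return cur


# ---------------------------------------------------------------------------
# Analytic FLOP formulas (printed-equation forms)
# ---------------------------------------------------------------------------

def _check_pos(**kw):
    for k, v in kw.items():
        if v <= 0:
            raise ArgumentError(f"{k} must be positive, got {v}")


def flops_wt(c_in: int, h: int, w: int, levels: int) -> int:
    """Wavelet-decomposition FLOPs: C_in * sum_{i=0}^{l-1} 4*H*W / 2^i."""
    _check_pos(c_in=c_in, h=h, w=w, levels=levels)
    return int(c_in * sum(4 * h * w / 2 ** i for i in range(levels)))


def flops_bands(c_in: int, c_out: int, h: int, w: int, k: int, levels: int) -> int:
    """Per-band convolution FLOPs as printed:
    sum_{i=1}^{l} (H*W / 2^i) * k^2 * 4 * C_in * C_out.

    Note this dense C_in x C_out form is the printed account; the WTConv
    operator itself applies depthwise kernels plus a 1x1 pointwise mix, and
    the model profiler costs the operator as implemented.
    """
    _check_pos(c_in=c_in, c_out=c_out, h=h, w=w, k=k, levels=levels)
    return int(sum(h * w / 2 ** i * k ** 2 * 4 * c_in * c_out
                   for i in range(1, levels + 1)))


def flops_iwt(c_out: int, h: int, w: int, levels: int) -> int:
    """Inverse-transform FLOPs: symmetric to :func:`flops_wt` with C_out."""
    _check_pos(c_out=c_out, h=h, w=w, levels=levels)
    return int(c_out * sum(4 * h * w / 2 ** i for i in range(levels)))


# ---------------------------------------------------------------------------
# The WTConv operator
# ---------------------------------------------------------------------------

@dataclass
class WTConvConfig:
    """Configuration of one WTConv operator.

    levels: wavelet decomposition depth (each level halves the map).
    band_kernel: odd depthwise kernel applied on every subband.
    base_kernel: odd depthwise kernel applied at full resolution.
    """

    channels: int
    levels: int = 2
    band_kernel: int = 3
    base_kernel: int = 5

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigError("WTConv: levels must be >= 1")
        if self.band_kernel % 2 == 0 or self.base_kernel % 2 == 0:
            raise ConfigError("WTConv: kernels must be odd")


class WTConv2d(nn.Module):
    """Depthwise wavelet-transform convolution (channel-preserving).

    forward(x) = base_dwconv(x) + IWT-cascade of per-band depthwise convs,
    recursing on the raw LL band for deeper levels.  Spatial size and
    channel count are preserved.
    """

    def __init__(self, cfg: WTConvConfig, adaptive: bool = False):
        super().__init__()
        self.cfg = cfg
        self.adaptive = adaptive
        c = cfg.channels
        self.base = nn.Conv2d(c, c, cfg.base_kernel, groups=c, bias=False)
        # one depthwise conv over the 4 stacked subbands per level
        self.bands = nn.ModuleList([
            nn.Conv2d(4 * c, 4 * c, cfg.band_kernel, groups=4 * c, bias=False)
            for _ in range(cfg.levels)
        ])

    def _effective_levels(self, h, w):
        """Levels usable so the smallest decomposed map stays >= 2x2.

        With ``adaptive=True`` (backbone use at reduced input sizes) the
        cascade is truncated; otherwise exceeding the depth is an error."""
        for lvl in range(self.cfg.levels):
            if min(h, w) < 2:
                if self.adaptive:
                    return lvl
                raise ConfigError(
                    f"WTConv: level {lvl} would decompose a {h}x{w} map; "
                    f"reduce levels for this input size")
            h, w = (h + 1) // 2, (w + 1) // 2
        return self.cfg.levels

    def _cascade(self, x, lvl):
        c = self.cfg.channels
        x, (h0, w0) = _pad_to_even(x)
        ll, lh, hl, hh = haar_dwt2(x)
        stack = concat([ll, lh, hl, hh], axis=1)
        conv = self.bands[lvl](stack)
        cll = conv[:, 0:c]
        clh = conv[:, c:2 * c]
        chl = conv[:, 2 * c:3 * c]
        chh = conv[:, 3 * c:4 * c]
        if lvl + 1 < self._levels_now:
            cll = cll + self._cascade(ll, lvl + 1)
        out = haar_idwt2((cll, clh, chl, chh))
        if out.shape[-2] != h0 or out.shape[-1] != w0:
            out = out[..., :h0, :w0]
        return out

    def forward(self, x):
        n, c, h, w = x.shape
        if c != self.cfg.channels:
            raise ConfigError(f"WTConv: expected {self.cfg.channels} channels, got {c}")
        self._levels_now = self._effective_levels(h, w)
        if x.is_meta:
            # transform cost per the printed formulas; band/base convs
            # count themselves through the conv primitive
            add_flops(n * (flops_wt(c, h, w, self._levels_now)
                           + flops_iwt(c, h, w, self._levels_now)))
        return self.base(x) + self._cascade(x, 0)


class WTConvBlock(nn.Module):
    """Drop-in replacement for a dense 3x3 conv: depthwise WTConv followed by
    a 1x1 pointwise channel mix, each with batch norm."""

    def __init__(self, cin, cout, levels=2, band_kernel=3, base_kernel=5, stride=1):
        super().__init__()
        self.wtconv = WTConv2d(WTConvConfig(cin, levels, band_kernel, base_kernel),
                               adaptive=True)
        self.bn1 = nn.BatchNorm2d(cin)
        # any downsampling rides on the pointwise mix
        self.pointwise = nn.Conv2d(cin, cout, 1, stride=stride, bias=False)

    def forward(self, x):
        return self.pointwise(self.bn1(self.wtconv(x)))


def wtconv2d(x, cfg: WTConvConfig, weights=None):
    """Functional WTConv: applies the operator with the given weights.

    ``weights`` maps {'base': (C,1,K,K), 'bands': [(4C,1,k,k), ...]}; when
    omitted the operator uses randomly initialised kernels.
    """
    op = WTConv2d(cfg)
    if weights is not None:
        op.base.weight.data = np.asarray(weights["base"], dtype=np.float32)
        for conv, wb in zip(op.bands, weights["bands"]):
            conv.weight.data = np.asarray(wb, dtype=np.float32)
    return op(ensure(x))
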