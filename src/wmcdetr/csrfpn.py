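"""Context-guided spatial feature reconstruction feature pyramid (CSRFPN).

The neck replaces the baseline cross-scale convolutional fusion with four
small modules:

* RCM (rectangular self-calibration) — axial average pooling broadcast back
  into a rectangular attention map, refined by two large-kernel depthwise
  strip convolutions, gating a depthwise 3x3 transform of the input;
* PCE (pyramid context extraction) — all three pyramid levels pooled to one
  coarse grid (stride 64 of the image), fused 1x1, refined by stacked RCMs;
* DIF (dynamic interpolation fusion) — bilinear resize + 1x1 channel match
  + elementwise add;
* MFF (multi-feature fusion) — a hard-sigmoid gate computed from the
  low-resolution map, upsampled and multiplied onto the convolved
  high-resolution map.

Wiring: context = PCE(P3, P4, P5); N5 = RCM(DIF(P5, context));
N4 = RCM(MFF(P4, N5)); N3 = RCM(MFF(P3, N4)).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nnkit as nn
from .errors import ConfigError
from .nnkit import Tensor


@dataclass
class NeckConfig:
    hidden: int = 256
    strip_kernel: int = 11
    pce_depth: int = 2
    pool_factors: tuple = (8, 4, 2)          # for (P3, P4, P5)
    # kernel of the conv on the high-res input of each MFF (P4 fusion, P3 fusion)
    mff_main_kernels: tuple = (3, 1)
    # kernel of the gate conv on the low-res input of each MFF
    mff_gate_kernels: tuple = (3, 3)

    def __post_init__(self):
        if self.strip_kernel % 2 == 0:
            raise ConfigError("RCM strip kernel must be odd")


class RCM(nn.Module):
    """Rectangular self-calibration: axial pooling -> strip convs -> gate."""

    def __init__(self, c, k=11):
        super().__init__()
        if k % 2 == 0:
            raise ConfigError("RCM strip kernel must be odd")
        self.c, self.k = c, k
        # edge-replication padding keeps the attention of a constant map
        # spatially uniform (zero padding would leak border artefacts)
        self.strip_h = nn.Conv2d(c, c, (1, k), padding=0, groups=c, bias=False)
        self.bn = nn.BatchNorm2d(c)
        self.strip_v = nn.Conv2d(c, c, (k, 1), padding=0, groups=c, bias=False)
        self.dw = nn.Conv2d(c, c, 3, groups=c)

    def _strip(self, conv, x, axis):
        p = self.k // 2
        pad = (0, 0, p, p) if axis == "h" else (p, p, 0, 0)
        return conv(nn.replicate_pad2d(x, pad))

    def attention(self, x):
        hp = x.mean(axis=2, keepdims=True)      # C x 1 x W
        vp = x.mean(axis=3, keepdims=True)      # C x H x 1
        rect = hp + vp                          # broadcast add -> C x H x W
        y = self._strip(self.strip_v,
                        nn.relu(self.bn(self._strip(self.strip_h, rect, "h"))),
                        "v")
        return nn.sigmoid(y)

    def forward(self, x):
        return self.dw(x) * self.attention(x)


class PCE(nn.Module):
    """Pool all levels to the shared coarse grid, fuse, refine with RCMs."""

    def __init__(self, cfg: NeckConfig):
        super().__init__()
        c = cfg.hidden
        self.cfg = cfg
        self.fuse = nn.Conv2d(3 * c, c, 1, bias=False)
        self.rcms = nn.ModuleList([RCM(c, cfg.strip_kernel)
                                   for _ in range(cfg.pce_depth)])

    def forward(self, p3, p4, p5):
        pooled = []
        for name, p, f in zip(("P3", "P4", "P5"), (p3, p4, p5), self.cfg.pool_factors):
            if p.shape[2] % f or p.shape[3] % f:
                raise ConfigError(
                    f"PCE: {name} spatial size {p.shape[2]}x{p.shape[3]} "
                    f"not divisible by pooling factor {f}")
            pooled.append(nn.avg_pool2d(p, f))
        ctx = self.fuse(nn.concat(pooled, axis=1))
        for rcm in self.rcms:
            ctx = rcm(ctx)
        return ctx


class DIF(nn.Module):
    """Resize low-res map to the high-res grid, 1x1 channel match, add."""

    def __init__(self, c0, c1):
        super().__init__()
        self.proj = nn.Conv2d(c1, c0, 1)

    def forward(self, x0, x1):
        up = nn.interpolate_bilinear(x1, (x0.shape[2], x0.shape[3]))
        return x0 + self.proj(up)


class MFF(nn.Module):
    """Hard-sigmoid gate from the low-res map modulating the high-res map."""

    def __init__(self, c, main_kernel=1, gate_kernel=1):
        super().__init__()
        self.main = nn.Conv2d(c, c, main_kernel)
        self.gate = nn.Conv2d(c, c, gate_kernel)

    def forward(self, xh, xl):
        g = nn.hsigmoid(self.gate(xl))
        g = nn.interpolate_bilinear(g, (xh.shape[2], xh.shape[3]))
        return g * self.main(xh)


class CSRFPN(nn.Module):
    """The full neck: context injection at P5, top-down gated fusion."""

    def __init__(self, cfg: NeckConfig | None = None):
        super().__init__()
        self.cfg = cfg or NeckConfig()
        c = self.cfg.hidden
        self.pce = PCE(self.cfg)
        self.dif5 = DIF(c, c)
        self.mff4 = MFF(c, self.cfg.mff_main_kernels[0], self.cfg.mff_gate_kernels[0])
        self.mff3 = MFF(c, self.cfg.mff_main_kernels[1], self.cfg.mff_gate_kernels[1])
        self.rcm5 = RCM(c, self.cfg.strip_kernel)
        self.rcm4 = RCM(c, self.cfg.strip_kernel)
        self.rcm3 = RCM(c, self.cfg.strip_kernel)

    def forward(self, p3, p4, p5):
        for name, p in (("P3", p3), ("P4", p4), ("P5", p5)):
            if p is None:
                raise ConfigError(f"CSRFPN: missing level {name}")
        ctx = self.pce(p3, p4, p5)
        n5 = self.rcm5(self.dif5(p5, ctx))
        n4 = self.rcm4(self.mff4(p4, n5))
        n3 = self.rcm3(self.mff3(p3, n4))
        return n3, n4, n5


def build_csrfpn(cfg: NeckConfig | None = None) -> CSRFPN:
    return CSRFPN(cfg)


# functional faces used by tests and docs
def rcm(x, k=11, module: RCM | None = None):
    mod = module or RCM(x.shape[1], k)
    return mod(x)


def pce(p3, p4, p5, cfg: NeckConfig | None = None, module: PCE | None = None):
    mod = module or PCE(cfg or NeckConfig(hidden=p3.shape[1]))
    return mod(p3, p4, p5)


def dif(x0, x1, module: DIF | None = None):
    mod = module or DIF(x0.shape[1], x1.shape[1])
    return mod(x0, x1)


def mff(xh, xl, module: MFF | None = None):
    mod = module or MFF(xh.shape[1])
    return mod(xh, xl)
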