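"""ResNet18 feature extractor and its wavelet-convolution variant.

The detector consumes three feature levels {P3, P4, P5} at strides
{8, 16, 32} with widths (128, 256, 512).  The wavelet variant swaps
designated 3x3 convolutions inside the residual blocks for a depthwise
WTConv followed by a 1x1 pointwise mix (:class:`~wmcdetr.wavelet.WTConvBlock`),
which buys the same receptive field (and more, through the subband cascade)
for a fraction of the parameters.

Replacement policies (which 3x3 convs become WTConv):

* ``"none"``      — plain ResNet18 (baseline detector);
* ``"second"``    — the second conv of every BasicBlock;
* ``"both"``      — both convs of every BasicBlock;
The shipped default for the wavelet variant is ``"second"``: this placement
is the one whose detector-level parameter/FLOP totals match the published
architecture profile (replacing both convolutions everywhere makes the
backbone far lighter than that profile).

Checkpoint key naming follows the module tree, e.g.
``stage3.block2.conv2.0.wtconv.base.weight`` and
``...wtconv.bands.<level>.weight`` for the per-level subband kernels
(prefixed with ``backbone.`` inside a full detector state dict).
"""

from __future__ import annotations

from dataclasses import dataclass

from . import nnkit as nn
from .errors import ConfigError
from .nnkit import Tensor
from .wavelet import WTConvBlock


@dataclass
class FeaturePyramid:
    """Backbone/neck outputs at strides 8, 16, 32."""

    p3: Tensor
    p4: Tensor
    p5: Tensor

    def as_list(self):
        return [self.p3, self.p4, self.p5]


#: named replacement policies -> {(stage_idx, block_idx): {conv indices}}
_POLICIES = {
    "none": {},
    "second": {(s, b): {2} for s in range(1, 5) for b in range(1, 3)},
    "both": {(s, b): {1, 2} for s in range(1, 5) for b in range(1, 3)},
}


@dataclass
class BackboneConfig:
    policy: str = "none"
    wt_levels: int = 2
    band_kernel: int = 3
    base_kernel: int = 5

    def replacement_map(self):
        if self.policy not in _POLICIES:
            raise ConfigError(
                f"unknown WTConv replacement policy {self.policy!r}; "
                f"known: {sorted(_POLICIES)}")
        return _POLICIES[self.policy]


class BasicBlock(nn.Module):
    def __init__(self, cin, cout, stride, replace, cfg: BackboneConfig):
        super().__init__()

        def make(idx, ci, co, s):
            if idx in replace:
                return nn.Sequential(
                    WTConvBlock(ci, co, cfg.wt_levels, cfg.band_kernel,
                                cfg.base_kernel, stride=s),
                    nn.BatchNorm2d(co))
            return nn.Sequential(nn.Conv2d(ci, co, 3, stride=s, bias=False),
                                 nn.BatchNorm2d(co))

        self.conv1 = make(1, cin, cout, stride)
        self.conv2 = make(2, cout, cout, 1)
        if stride != 1 or cin != cout:
            self.down = nn.Sequential(nn.Conv2d(cin, cout, 1, stride=stride, bias=False),
                                      nn.BatchNorm2d(cout))
        else:
            self.down = None

    def forward(self, x):
        y = nn.relu(self.conv1(x))
        y = self.conv2(y)
        skip = self.down(x) if self.down is not None else x
        return nn.relu(y + skip)


class Stage(nn.Module):
    def __init__(self, sidx, cin, cout, stride, cfg):
        super().__init__()
        rep = cfg.replacement_map()
        self.block1 = BasicBlock(cin, cout, stride, rep.get((sidx, 1), set()), cfg)
        self.block2 = BasicBlock(cout, cout, 1, rep.get((sidx, 2), set()), cfg)

    def forward(self, x):
        return self.block2(self.block1(x))


class ResNet18Backbone(nn.Module):
    """Stem + 4 stages of 2 BasicBlocks; emits {P3, P4, P5}."""

    def __init__(self, cfg: BackboneConfig | None = None):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.cfg = cfg
        self.stem = nn.Sequential(nn.Conv2d(3, 64, 7, stride=2, bias=False),
                                  nn.BatchNorm2d(64), nn.ReLU(),
                                  nn.MaxPool2d(3, 2, 1))
        self.stage1 = Stage(1, 64, 64, 1, cfg)
        self.stage2 = Stage(2, 64, 128, 2, cfg)
        self.stage3 = Stage(3, 128, 256, 2, cfg)
        self.stage4 = Stage(4, 256, 512, 2, cfg)
        self.out_channels = (128, 256, 512)

    def forward(self, x) -> FeaturePyramid:
        x = self.stem(x)
        x = self.stage1(x)
        p3 = self.stage2(x)
        p4 = self.stage3(p3)
        p5 = self.stage4(p4)
        return FeaturePyramid(p3, p4, p5)


def build_wt_backbone(cfg: BackboneConfig | str = "second") -> ResNet18Backbone:
    """Build the wavelet-convolution backbone (or baseline with policy 'none')."""
    if isinstance(cfg, str):
        cfg = BackboneConfig(policy=cfg)
    return ResNet18Backbone(cfg)
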