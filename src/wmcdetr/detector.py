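"""End-to-end detector assembly, training and inference.

Two assemblies share one decoder design:

* baseline — ResNet18 backbone, AIFI (plain MHSA) on the stride-32 level,
  convolutional cross-scale fusion neck (CCFF with CSP/RepVGG blocks);
* improved — WTConv backbone, M2SA-AIFI, CSRFPN neck.

The decoder is DETR-style and NMS-free: the encoder memory proposes
queries (top-k by class confidence), three decoder layers refine them with
multi-scale deformable cross-attention, and Hungarian matching assigns
predictions to ground truth for the classification + L1 + GIoU loss, with
noised ground-truth (denoising) queries stabilising early training.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nnkit as nn
from .backbone import BackboneConfig, FeaturePyramid, ResNet18Backbone
from .csrfpn import CSRFPN, NeckConfig
from .errors import ArgumentError, ConfigError
from .m2sa import AIFILayer, M2SAConfig, MultiHeadAttention
from .nnkit import Tensor
from .nnkit.tensor import concat

VARIANTS = ("baseline", "wtconv_only", "m2sa_only", "wtconv+m2sa",
            "csrfpn_only", "full")


@dataclass
class ModelConfig:
    """One-to-one with the ablation grid: which of the three improvements
    (WTConv backbone / M2SA encoder attention / CSRFPN neck) are active."""

    variant: str = "full"
    hidden: int = 256
    decoder_layers: int = 3
    queries: int = 300
    dn_queries: int = 100
    input_size: int = 640
    num_classes: int = 2
    heads: int = 8
    dec_points: int = 4
    aifi_ffn: int = 1024
    dec_ffn: int = 1024
    ccff_expansion: float = 0.5
    ccff_depth: int = 3
    backbone: BackboneConfig | None = None
    neck: NeckConfig | None = None
    m2sa: M2SAConfig | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}; known: {VARIANTS}")
        wt = self.variant in ("wtconv_only", "wtconv+m2sa", "full")
        if self.backbone is None:
            self.backbone = BackboneConfig(policy="second" if wt else "none")
        elif wt != (self.backbone.policy != "none"):
            raise ConfigError(f"variant {self.variant} inconsistent with backbone "
                              f"policy {self.backbone.policy!r}")
        if self.use_csrfpn and self.neck is None:
            self.neck = NeckConfig(hidden=self.hidden)
        if self.use_m2sa and self.m2sa is None:
            self.m2sa = M2SAConfig(hidden=self.hidden, heads=self.heads)

    @property
    def use_m2sa(self):
        return self.variant in ("m2sa_only", "wtconv+m2sa", "full")

    @property
    def use_csrfpn(self):
        return self.variant in ("csrfpn_only", "full")


@dataclass
class DetectionSet:
    """Per-image predictions: boxes in xyxy pixels, clipped to bounds."""

    boxes: np.ndarray          # (K, 4)
    scores: np.ndarray         # (K,)
    class_ids: np.ndarray      # (K,)
    image_id: int = 0


# ---------------------------------------------------------------------------
# box arithmetic
# ---------------------------------------------------------------------------

def giou(a, b):
    """Generalised IoU of two xyxy boxes, in (-1, 1]."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    if ax2 <= ax1 or ay2 <= ay1 or bx2 <= bx1 or by2 <= by1:
        raise ArgumentError(f"degenerate box in giou: {a} vs {b}")
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    hull = (max(ax2, bx2) - min(ax1, bx1)) * (max(ay2, by2) - min(ay1, by1))
    iou = inter / union if union > 0 else 0.0
    return iou - (hull - union) / hull


def _pairwise_iou_giou(a, b):
    """Vectorised IoU and GIoU between (M,4) and (N,4) xyxy arrays."""
    a = a[:, None]
    b = b[None]
    iw = np.clip(np.minimum(a[..., 2], b[..., 2]) - np.maximum(a[..., 0], b[..., 0]), 0, None)
    ih = np.clip(np.minimum(a[..., 3], b[..., 3]) - np.maximum(a[..., 1], b[..., 1]), 0, None)
    inter = iw * ih
    area_a = (a[..., 2] - a[..., 0]) * (a[..., 3] - a[..., 1])
    area_b = (b[..., 2] - b[..., 0]) * (b[..., 3] - b[..., 1])
    union = area_a + area_b - inter
    iou = np.where(union > 0, inter / np.maximum(union, 1e-9), 0.0)
    hw = np.maximum(a[..., 2], b[..., 2]) - np.minimum(a[..., 0], b[..., 0])
    hh = np.maximum(a[..., 3], b[..., 3]) - np.minimum(a[..., 1], b[..., 1])
    hull = np.maximum(hw * hh, 1e-9)
    return iou, iou - (hull - union) / hull


def _cxcywh_to_xyxy(t):
    cx, cy, w, h = t[..., 0], t[..., 1], t[..., 2], t[..., 3]
    return np.stack([cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2], axis=-1)


def hungarian_assign(cost):
    """Minimum-cost one-to-one assignment on an (n_pred, n_gt) cost matrix."""
    if cost.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return linear_sum_assignment(cost)


def hungarian_match(pred_boxes, pred_probs, gt_boxes, gt_labels,
                    cost_weights=(2.0, 5.0, 2.0)):
    """Optimal one-to-one assignment of predictions to ground truth.

    pred_boxes: (Q, 4) normalised cxcywh; pred_probs: (Q, nc) class
    probabilities; gt_boxes: (G, 4) normalised cxcywh.  Returns (pred_idx,
    gt_idx) arrays; queries not listed are background.
    """
    if len(gt_boxes) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    wc, wl1, wg = cost_weights
    cost_class = -pred_probs[:, gt_labels]
    l1 = np.abs(pred_boxes[:, None] - gt_boxes[None]).sum(-1)
    _, g = _pairwise_iou_giou(_cxcywh_to_xyxy(pred_boxes), _cxcywh_to_xyxy(gt_boxes))
    cost = wc * cost_class + wl1 * l1 + wg * (-g)
    return hungarian_assign(cost)


def _inv_sigmoid(x, eps=1e-4):
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


# ---------------------------------------------------------------------------
# baseline CCFF neck
# ---------------------------------------------------------------------------

class RepVGGBlock(nn.Module):
    """Train-time RepVGG unit: 3x3 conv-BN + 1x1 conv-BN, summed, SiLU."""

    def __init__(self, c):
        super().__init__()
        self.conv3 = nn.ConvBNAct(c, c, 3, act="none")
        self.conv1 = nn.ConvBNAct(c, c, 1, act="none")

    def forward(self, x):
        return nn.silu(self.conv3(x) + self.conv1(x))


class CSPRepLayer(nn.Module):
    def __init__(self, cin, cout, n=3, expansion=0.5):
        super().__init__()
        hidden = int(cout * expansion)
        self.conv1 = nn.ConvBNAct(cin, hidden, 1, act="silu")
        self.conv2 = nn.ConvBNAct(cin, hidden, 1, act="silu")
        self.blocks = nn.Sequential(*[RepVGGBlock(hidden) for _ in range(n)])
        self.conv3 = (nn.ConvBNAct(hidden, cout, 1, act="silu")
                      if hidden != cout else nn.Identity())

    def forward(self, x):
        return self.conv3(self.blocks(self.conv1(x)) + self.conv2(x))


class CCFF(nn.Module):
    """Baseline cross-scale fusion: top-down FPN then bottom-up PAN path."""

    def __init__(self, hidden=256, expansion=0.5, depth=3):
        super().__init__()
        c = hidden
        self.lat5 = nn.ConvBNAct(c, c, 1, act="silu")
        self.fpn4 = CSPRepLayer(2 * c, c, depth, expansion)
        self.lat4 = nn.ConvBNAct(c, c, 1, act="silu")
        self.fpn3 = CSPRepLayer(2 * c, c, depth, expansion)
        self.down3 = nn.ConvBNAct(c, c, 3, stride=2, act="silu")
        self.pan4 = CSPRepLayer(2 * c, c, depth, expansion)
        self.down4 = nn.ConvBNAct(c, c, 3, stride=2, act="silu")
        self.pan5 = CSPRepLayer(2 * c, c, depth, expansion)

    def forward(self, p3, p4, p5):
        l5 = self.lat5(p5)
        up5 = nn.interpolate_bilinear(l5, (p4.shape[2], p4.shape[3]))
        f4 = self.fpn4(concat([up5, p4], axis=1))
        l4 = self.lat4(f4)
        up4 = nn.interpolate_bilinear(l4, (p3.shape[2], p3.shape[3]))
        n3 = self.fpn3(concat([up4, p3], axis=1))
        m4 = self.pan4(concat([self.down3(n3), l4], axis=1))
        n5 = self.pan5(concat([self.down4(m4), l5], axis=1))
        return n3, m4, n5


class HybridEncoder(nn.Module):
    """Input projection + AIFI on the top level + cross-scale neck."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c = cfg.hidden
        self.proj3 = nn.ConvBNAct(128, c, 1, act="none")
        self.proj4 = nn.ConvBNAct(256, c, 1, act="none")
        self.proj5 = nn.ConvBNAct(512, c, 1, act="none")
        self.aifi = AIFILayer(hidden=c, heads=cfg.heads, ffn=cfg.aifi_ffn,
                              attn="m2sa" if cfg.use_m2sa else "mhsa",
                              m2sa_cfg=cfg.m2sa)
        if cfg.use_csrfpn:
            self.neck = CSRFPN(cfg.neck)
        else:
            self.neck = CCFF(c, cfg.ccff_expansion, cfg.ccff_depth)

    def forward(self, pyramid: FeaturePyramid):
        p3 = self.proj3(pyramid.p3)
        p4 = self.proj4(pyramid.p4)
        p5 = self.aifi(self.proj5(pyramid.p5))
        return self.neck(p3, p4, p5)


# ---------------------------------------------------------------------------
# deformable decoder
# ---------------------------------------------------------------------------

class MSDeformableAttention(nn.Module):
    """Multi-scale deformable attention over the flattened encoder memory."""

    def __init__(self, dim=256, heads=8, levels=3, points=4):
        super().__init__()
        self.dim, self.heads, self.levels, self.points = dim, heads, levels, points
        self.dk = dim // heads
        self.offsets = nn.Linear(dim, heads * levels * points * 2)
        self.weights = nn.Linear(dim, heads * levels * points)
        self.value_proj = nn.Linear(dim, dim)
        self.out_proj = nn.Linear(dim, dim)
        # spread initial sampling offsets on a ring, one direction per head
        theta = np.arange(heads) * 2 * math.pi / heads
        grid = np.stack([np.cos(theta), np.sin(theta)], -1)
        grid /= np.abs(grid).max(-1, keepdims=True)
        init = np.tile(grid[:, None, None], (1, levels, points, 1))
        init *= np.arange(1, points + 1)[None, None, :, None]
        self.offsets.weight.data[:] = 0
        self.offsets.bias.data = init.reshape(-1).astype(np.float32)

    def forward(self, query, ref_boxes, value_levels, spatial_shapes):
        """query (N, Q, C); ref_boxes (N, Q, 4) normalised cxcywh;
        value_levels: list of (N, Hl*Wl, C) memory per level."""
        n, q, c = query.shape
        h_, l_, p_ = self.heads, self.levels, self.points
        off = self.offsets(query).reshape(n, q, h_, l_, p_, 2)
        w = nn.softmax(self.weights(query).reshape(n, q, h_, l_ * p_), axis=-1)
        w = w.reshape(n, q, h_, l_, p_)

        if query.is_meta:
            # sampling itself is gather-only; value/out projections count
            for v in value_levels:
                self.value_proj(v)
            self.out_proj(query)
            return query * 1.0

        centre = ref_boxes.data[:, :, None, None, None, :2]
        wh = ref_boxes.data[:, :, None, None, None, 2:]
        locs = off * (1.0 / p_) * Tensor(wh * 0.5) + Tensor(centre)

        per_level = []
        for li, (v, (hl, wl)) in enumerate(zip(value_levels, spatial_shapes)):
            vp = self.value_proj(v)                           # (N, HW, C)
            vm = vp.reshape(n, hl * wl, h_, self.dk).transpose(0, 2, 3, 1) \
                   .reshape(n * h_, self.dk, hl, wl)
            pts = locs[:, :, :, li].transpose(0, 2, 1, 3, 4) \
                      .reshape(n * h_, q * p_, 2)
            sampled = nn.point_sample(vm, pts)                # (N*h, dk, Q*P)
            sampled = sampled.reshape(n, h_, self.dk, q, p_)
            wl_t = w[:, :, :, li].transpose(0, 2, 1, 3)        # (N, h, Q, P)
            weighted = (sampled * wl_t.reshape(n, h_, 1, q, p_)).sum(axis=4)
            per_level.append(weighted)                        # (N, h, dk, Q)
        agg = per_level[0]
        for t in per_level[1:]:
            agg = agg + t
        out = agg.reshape(n, c, q).transpose(0, 2, 1)
        return self.out_proj(out)


class DecoderLayer(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c = cfg.hidden
        self.self_attn = MultiHeadAttention(c, cfg.heads)
        self.norm1 = nn.LayerNorm(c)
        self.cross_attn = MSDeformableAttention(c, cfg.heads, 3, cfg.dec_points)
        self.norm2 = nn.LayerNorm(c)
        self.ffn1 = nn.Linear(c, cfg.dec_ffn)
        self.ffn2 = nn.Linear(cfg.dec_ffn, c)
        self.norm3 = nn.LayerNorm(c)

    def forward(self, tgt, qpos, ref_boxes, value_levels, shapes, attn_mask=None):
        qk = tgt + qpos
        tgt = self.norm1(tgt + self.self_attn(qk, qk, tgt, mask=attn_mask))
        tgt = self.norm2(tgt + self.cross_attn(tgt + qpos, ref_boxes,
                                               value_levels, shapes))
        return self.norm3(tgt + self.ffn2(nn.relu(self.ffn1(tgt))))


class Decoder(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        c, nc = cfg.hidden, cfg.num_classes
        self.cfg = cfg
        self.layers = nn.ModuleList([DecoderLayer(cfg) for _ in range(cfg.decoder_layers)])
        self.query_pos_head = nn.MLP(4, 2 * c, c, 2)
        self.class_heads = nn.ModuleList([nn.Linear(c, nc) for _ in range(cfg.decoder_layers)])
        self.bbox_heads = nn.ModuleList([nn.MLP(c, c, 4, 3) for _ in range(cfg.decoder_layers)])
        bias0 = -math.log((1 - 0.01) / 0.01)
        for head in self.class_heads:
            head.bias.data[:] = bias0
        for head in self.bbox_heads:
            head.layers[-1].weight.data[:] = 0
            head.layers[-1].bias.data[:] = 0

    def forward(self, tgt, ref_boxes_np, value_levels, shapes, attn_mask=None):
        """Returns per-layer (class logits Tensor, boxes Tensor (sigmoid))."""
        outputs = []
        ref = ref_boxes_np                    # numpy, detached by construction
        for layer, chead, bhead in zip(self.layers, self.class_heads, self.bbox_heads):
            ref_t = Tensor(ref.astype(np.float32)) if not tgt.is_meta else None
            qpos = self.query_pos_head(Tensor(ref.astype(np.float32))
                                       if not tgt.is_meta else nn.meta(ref.shape))
            tgt = layer(tgt, qpos, ref_t if ref_t is not None else nn.meta(ref.shape),
                        value_levels, shapes, attn_mask)
            logits = chead(tgt)
            delta = bhead(tgt)
            if tgt.is_meta:
                outputs.append((logits, delta))
                continue
            boxes = nn.sigmoid(delta + Tensor(_inv_sigmoid(ref).astype(np.float32)))
            outputs.append((logits, boxes))
            ref = boxes.data.copy()           # detached refinement
        return outputs


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

class WMCRTDETR(nn.Module):
    """NMS-free detector; ``variant`` picks the ablation configuration."""

    def __init__(self, cfg: ModelConfig | None = None, seed=0):
        super().__init__()
        nn.seed_init(seed)
        self.cfg = cfg or ModelConfig()
        c = self.cfg.hidden
        self.backbone = ResNet18Backbone(self.cfg.backbone)
        self.encoder = HybridEncoder(self.cfg)
        self.enc_output = nn.Linear(c, c)
        self.enc_norm = nn.LayerNorm(c)
        self.enc_class = nn.Linear(c, self.cfg.num_classes)
        self.enc_bbox = nn.MLP(c, c, 4, 3)
        self.enc_class.bias.data[:] = -math.log((1 - 0.01) / 0.01)
        self.enc_bbox.layers[-1].weight.data[:] = 0
        self.enc_bbox.layers[-1].bias.data[:] = 0
        self.decoder = Decoder(self.cfg)
        self.dn_class_embed = nn.Parameter(
            np.random.default_rng(seed + 1).normal(0, 0.02,
                                                   (self.cfg.num_classes, c)))
        self._anchor_cache = {}

    # -- anchors ------------------------------------------------------------
    def _anchors(self, shapes):
        key = tuple(shapes)
        if key in self._anchor_cache:
            return self._anchor_cache[key]
        all_anchors, valid = [], []
        for lvl, (h, w) in enumerate(shapes):
            gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
            cx = (gx.reshape(-1) + 0.5) / w
            cy = (gy.reshape(-1) + 0.5) / h
            wh = np.full_like(cx, 0.05 * 2 ** lvl)
            a = np.stack([cx, cy, wh, wh], -1)
            all_anchors.append(a)
            valid.append(((a > 0.01) & (a < 0.99)).all(-1))
        anchors = np.concatenate(all_anchors, 0).astype(np.float32)
        valid = np.concatenate(valid, 0)
        logit = _inv_sigmoid(anchors)
        self._anchor_cache[key] = (logit, valid)
        return logit, valid

    # -- forward ------------------------------------------------------------
    def forward(self, images, dn=None):
        """images: Tensor (N, 3, H, W) in [0, 1].  Returns a dict with
        per-layer decoder outputs, encoder proposals and dn outputs."""
        n = images.shape[0]
        feats = self.encoder(self.backbone(images))
        shapes = [(f.shape[2], f.shape[3]) for f in feats]
        tokens = [f.reshape(n, self.cfg.hidden, h * w).transpose(0, 2, 1)
                  for f, (h, w) in zip(feats, shapes)]
        memory = concat(tokens, axis=1)
        mem_feat = self.enc_norm(self.enc_output(memory))
        enc_logits = self.enc_class(mem_feat)
        anchor_logit, valid = self._anchors(shapes)
        enc_delta = self.enc_bbox(mem_feat)

        if images.is_meta:
            # meta path: emulate selection shapes for profiling
            tgt = nn.meta((n, self.cfg.queries, self.cfg.hidden))
            ref = np.zeros((n, self.cfg.queries, 4), dtype=np.float32)
            outs = self.decoder(tgt, ref, tokens, shapes)
            return {"decoder": outs, "enc_logits": enc_logits,
                    "enc_boxes": enc_delta}

        enc_box_logit = enc_delta + Tensor(anchor_logit[None])
        enc_boxes = nn.sigmoid(enc_box_logit)
        # uncertainty-minimal proposal scoring: classification confidence of
        # anchor-valid positions (invalid anchors are excluded)
        probs = 1.0 / (1.0 + np.exp(-enc_logits.data))
        score = probs.max(-1)
        score[:, ~valid] = -1.0
        k = min(self.cfg.queries, score.shape[1])
        topk = np.argsort(-score, axis=1)[:, :k]

        batch_idx = np.arange(n)[:, None]
        tgt = mem_feat.detach()[batch_idx, topk]          # content queries
        ref = enc_boxes.data[batch_idx, topk].copy()      # detached refs
        sel_logits = enc_logits[batch_idx, topk]
        sel_boxes = enc_boxes[batch_idx, topk]

        attn_mask = None
        dn_meta = None
        if dn is not None and dn["count"] > 0:
            dn_tgt, dn_ref, attn_mask, dn_meta = self._build_dn(dn, k, n)
            tgt = concat([dn_tgt, tgt], axis=1)
            ref = np.concatenate([dn_ref, ref], axis=1)

        outs = self.decoder(tgt, ref, tokens, shapes, attn_mask)
        return {"decoder": outs, "enc_logits": sel_logits, "enc_boxes": sel_boxes,
                "dn_meta": dn_meta, "num_queries": k}

    def _build_dn(self, dn, k, n):
        """Positive denoising queries: noised gt boxes, class-embed content."""
        labels, boxes, groups, per_img = dn["labels"], dn["boxes"], dn["groups"], dn["per_image"]
        total = dn["count"]
        emb = self.dn_class_embed[labels.reshape(-1)].reshape(n, total, self.cfg.hidden)
        dn_ref = boxes
        L = total + k
        mask = np.zeros((L, L), dtype=np.float32)
        neg = np.float32(-1e9)
        gsize = total // groups
        for g in range(groups):
            s, e = g * gsize, (g + 1) * gsize
            mask[s:e, :s] = neg
            mask[s:e, e:total] = neg
        mask[total:, :total] = neg      # matching queries never see dn tokens
        meta = {"count": total, "groups": groups, "per_image": per_img,
                "labels": labels, "gt_index": dn["gt_index"]}
        return emb, dn_ref, mask, meta


def build_model(cfg: ModelConfig | str | None = None, seed=0) -> WMCRTDETR:
    if isinstance(cfg, str):
        cfg = ModelConfig(variant=cfg)
    return WMCRTDETR(cfg or ModelConfig(), seed=seed)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _focal_bce(logits, target_onehot, alpha=0.25, gamma=2.0):
    """Sigmoid focal loss summed over classes/queries (Tensor graph)."""
    p = nn.sigmoid(logits)
    t = Tensor(target_onehot)
    # bce = -t log p - (1-t) log (1-p), focal-weighted; numerically via
    # softplus-free composition on clipped probabilities
    pc = nn.clip(p, 1e-6, 1 - 1e-6)
    ce = (t * nn.log(pc) + (1.0 - t) * nn.log(1.0 - pc)) * -1.0
    pt = t * pc + (1.0 - t) * (1.0 - pc)
    wt = (1.0 - pt) ** gamma
    alpha_t = alpha * target_onehot + (1 - alpha) * (1 - target_onehot)
    return (ce * wt * Tensor(alpha_t)).sum()


def _giou_loss_terms(pred_boxes, gt_xyxy):
    """Differentiable GIoU of matched pairs: pred (M,4) cxcywh Tensor."""
    px1 = pred_boxes[:, 0] - pred_boxes[:, 2] * 0.5
    py1 = pred_boxes[:, 1] - pred_boxes[:, 3] * 0.5
    px2 = pred_boxes[:, 0] + pred_boxes[:, 2] * 0.5
    py2 = pred_boxes[:, 1] + pred_boxes[:, 3] * 0.5
    gx1, gy1, gx2, gy2 = [Tensor(gt_xyxy[:, i].astype(np.float32)) for i in range(4)]

    def tmin(a, b):
        return (a + b - ((a - b) ** 2 + 1e-12) ** 0.5) * 0.5

    def tmax(a, b):
        return (a + b + ((a - b) ** 2 + 1e-12) ** 0.5) * 0.5

    iw = nn.relu(tmin(px2, gx2) - tmax(px1, gx1))
    ih = nn.relu(tmin(py2, gy2) - tmax(py1, gy1))
    inter = iw * ih
    area_p = nn.relu(px2 - px1) * nn.relu(py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter + 1e-9
    hw = tmax(px2, gx2) - tmin(px1, gx1)
    hh = tmax(py2, gy2) - tmin(py1, gy1)
    hull = hw * hh + 1e-9
    g = inter / union - (hull - union) / hull
    return (1.0 - g).sum()


LOSS_WEIGHTS = {"class": 1.0, "l1": 5.0, "giou": 2.0}


def detection_loss(outputs, targets, num_classes, dn_meta=None):
    """Hungarian-matched loss over all decoder layers + encoder head + dn.

    targets: list per image of (gt_boxes_cxcywh_norm (G,4), labels (G,)).
    Returns (total_loss Tensor, dict of floats).
    """
    total = None
    logs = {}
    n_img = len(targets)
    num_gts = max(1, sum(len(t[0]) for t in targets))

    def accumulate(loss):
        nonlocal total
        total = loss if total is None else total + loss

    def layer_loss(logits, boxes, tag, matched_idx=None):
        cls_tgt = np.zeros(logits.shape, dtype=np.float32)
        sel_rows, sel_gt_xyxy, sel_gt_cxcywh = [], [], []
        for i, (gt_b, gt_l) in enumerate(targets):
            if matched_idx is None:
                probs = 1.0 / (1.0 + np.exp(-logits.data[i]))
                pi, gi = hungarian_match(boxes.data[i], probs, gt_b, gt_l)
            else:
                pi, gi = matched_idx[i]
            if len(pi) == 0:
                continue
            cls_tgt[i, pi, gt_l[gi]] = 1.0
            for p, g in zip(pi, gi):
                sel_rows.append((i, p))
                sel_gt_cxcywh.append(gt_b[g])
                sel_gt_xyxy.append(_cxcywh_to_xyxy(gt_b[g][None])[0])
        cls_loss = _focal_bce(logits, cls_tgt) * (1.0 / num_gts)
        accumulate(cls_loss * LOSS_WEIGHTS["class"])
        logs[f"{tag}_class"] = float(cls_loss.data)
        if sel_rows:
            rows = np.array(sel_rows)
            sel = boxes[rows[:, 0], rows[:, 1]]
            gt_c = np.stack(sel_gt_cxcywh)
            l1 = (abs(sel - Tensor(gt_c.astype(np.float32)))).sum() * (1.0 / num_gts)
            gl = _giou_loss_terms(sel, np.stack(sel_gt_xyxy)) * (1.0 / num_gts)
            accumulate(l1 * LOSS_WEIGHTS["l1"] + gl * LOSS_WEIGHTS["giou"])
            logs[f"{tag}_l1"] = float(l1.data)
            logs[f"{tag}_giou"] = float(gl.data)

    dn_count = dn_meta["count"] if dn_meta else 0
    for li, (logits, boxes) in enumerate(outputs["decoder"]):
        m_logits = logits[:, dn_count:] if dn_count else logits
        m_boxes = boxes[:, dn_count:] if dn_count else boxes
        layer_loss(m_logits, m_boxes, f"dec{li}")
        if dn_count:
            dn_logits = logits[:, :dn_count]
            dn_boxes = boxes[:, :dn_count]
            matched = []
            for i, (gt_b, gt_l) in enumerate(targets):
                gi = dn_meta["gt_index"][i]
                pi = np.nonzero(gi >= 0)[0]
                matched.append((pi, gi[pi]))
            layer_loss(dn_logits, dn_boxes, f"dn{li}", matched_idx=matched)
    layer_loss(outputs["enc_logits"], outputs["enc_boxes"], "enc")
    logs["total"] = float(total.data)
    return total, logs


def build_dn_batch(targets, dn_queries, num_classes, rng,
                   box_noise=0.4):
    """Construct positive denoising queries for a batch.

    Returns dict with labels (N, T), boxes (N, T, 4), groups, gt_index
    (N, T) mapping each dn slot to its gt (or -1 for padding).
    """
    n = len(targets)
    max_gt = max((len(t[0]) for t in targets), default=0)
    if max_gt == 0 or dn_queries <= 0:
        return {"count": 0}
    groups = max(1, dn_queries // max_gt)
    total = groups * max_gt
    labels = np.zeros((n, total), dtype=np.int64)
    boxes = np.zeros((n, total, 4), dtype=np.float32)
    gt_index = np.full((n, total), -1, dtype=np.int64)
    for i, (gt_b, gt_l) in enumerate(targets):
        g = len(gt_b)
        for grp in range(groups):
            for j in range(max_gt):
                slot = grp * max_gt + j
                if j >= g:
                    boxes[i, slot] = (0.5, 0.5, 0.1, 0.1)
                    continue
                b = gt_b[j].copy()
                shift = (rng.random(2) * 2 - 1) * box_noise * b[2:] * 0.5
                scale = 1 + (rng.random(2) * 2 - 1) * box_noise
                b[:2] = np.clip(b[:2] + shift, 1e-3, 1 - 1e-3)
                b[2:] = np.clip(b[2:] * scale, 1e-3, 1)
                boxes[i, slot] = b
                labels[i, slot] = gt_l[j]
                gt_index[i, slot] = j
    return {"count": total, "groups": groups, "per_image": max_gt,
            "labels": labels, "boxes": boxes, "gt_index": gt_index}


# ---------------------------------------------------------------------------
# data plumbing, training, inference
# ---------------------------------------------------------------------------

def letterbox(image, size):
    """Resize with preserved aspect ratio and grey padding.

    Returns (out HxWx3 float in [0,1], scale, (pad_x, pad_y))."""
    h, w = image.shape[:2]
    s = size / max(h, w)
    nh, nw = int(round(h * s)), int(round(w * s))
    from PIL import Image as PILImage
    im = PILImage.fromarray(image).resize((nw, nh), PILImage.BILINEAR)
    out = np.full((size, size, 3), 114, dtype=np.uint8)
    py, px = (size - nh) // 2, (size - nw) // 2
    out[py:py + nh, px:px + nw] = np.asarray(im)
    return out.astype(np.float32) / 255.0, s, (px, py)


def records_to_batch(records, size):
    """Stack records into (N,3,S,S) [0,1] + normalised cxcywh targets."""
    imgs, targets = [], []
    for r in records:
        img, s, (px, py) = letterbox(r.image, size)
        imgs.append(img.transpose(2, 0, 1))
        if r.boxes:
            b = np.array([bb.as_tuple() for bb in r.boxes], dtype=np.float32)
            b = b * s
            b[:, [0, 2]] += px
            b[:, [1, 3]] += py
            cxcywh = np.stack([(b[:, 0] + b[:, 2]) / 2 / size,
                               (b[:, 1] + b[:, 3]) / 2 / size,
                               (b[:, 2] - b[:, 0]) / size,
                               (b[:, 3] - b[:, 1]) / size], -1)
            labels = np.array([bb.class_id for bb in r.boxes], dtype=np.int64)
        else:
            cxcywh = np.zeros((0, 4), dtype=np.float32)
            labels = np.zeros(0, dtype=np.int64)
        targets.append((cxcywh, labels))
    return np.stack(imgs), targets


@dataclass
class TrainConfig:
    epochs: int = 5
    batch_size: int = 4
    lr: float = 1e-4
    weight_decay: float = 1e-4
    grad_clip: float = 0.1
    seed: int = 0
    input_size: int | None = None    # defaults to model input size
    use_denoising: bool = True
    log_path: str | None = None


def save_checkpoint(model, path, half=False):
    state = model.state_dict()
    if half:
        state = {k: v.astype(np.float16) for k, v in state.items()}
    np.savez(path, **state)


def load_checkpoint(model, path):
    with np.load(path) as data:
        model.load_state_dict({k: data[k].astype(np.float32) for k in data.files})


def train(model, records, hyper: TrainConfig | None = None, iterations=None):
    """Desk-scale training loop (AdamW, Hungarian loss, denoising queries).

    ``records`` is a list of SampleRecords (typically a manifest's train
    split).  ``iterations`` caps total optimizer steps (overrides epochs).
    Emits one JSON line per epoch; aborts on NaN keeping the last-good state.
    """
    hyper = hyper or TrainConfig()
    size = hyper.input_size or model.cfg.input_size
    rng = np.random.default_rng(hyper.seed)
    opt = nn.AdamW(model.parameters(), lr=hyper.lr,
                   weight_decay=hyper.weight_decay, grad_clip=hyper.grad_clip)
    model.train()
    log_lines = []
    last_good = {k: v.copy() for k, v in model.state_dict().items()}
    step = 0
    history = []
    max_steps = iterations if iterations is not None else hyper.epochs * max(
        1, len(records) // hyper.batch_size)
    epoch = 0
    while step < max_steps:
        order = rng.permutation(len(records))
        epoch_losses = []
        for s in range(0, len(order), hyper.batch_size):
            if step >= max_steps:
                break
            batch = [records[i] for i in order[s:s + hyper.batch_size]]
            imgs, targets = records_to_batch(batch, size)
            dn = (build_dn_batch(targets, model.cfg.dn_queries,
                                 model.cfg.num_classes, rng)
                  if hyper.use_denoising else None)
            out = model(Tensor(imgs), dn=dn)
            loss, logs = detection_loss(out, targets, model.cfg.num_classes,
                                        out.get("dn_meta"))
            if not np.isfinite(loss.data):
                model.load_state_dict(last_good)
                line = {"epoch": epoch, "step": step, "event": "nan-abort"}
                log_lines.append(json.dumps(line))
                _flush_log(hyper.log_path, log_lines)
                return {"aborted": True, "history": history, "log": log_lines}
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(logs["total"])
            history.append(logs["total"])
            step += 1
        last_good = {k: v.copy() for k, v in model.state_dict().items()}
        line = {"epoch": epoch, "step": step,
                "loss": float(np.mean(epoch_losses)) if epoch_losses else None}
        log_lines.append(json.dumps(line))
        epoch += 1
    _flush_log(hyper.log_path, log_lines)
    model.eval()
    return {"aborted": False, "history": history, "log": log_lines}


def _flush_log(path, lines):
    if path:
        Path(path).write_text("\n".join(lines) + "\n")


def predict(model, images, score_threshold=0.3):
    """Run inference; returns one DetectionSet per image (no NMS anywhere).

    ``images`` is a list of HxWx3 uint8 arrays of any size (letterboxed to
    the model's input size; boxes are mapped back to original pixels and
    clipped)."""
    model.eval()
    size = model.cfg.input_size
    results = []
    for idx, image in enumerate(images):
        img, s, (px, py) = letterbox(image, size)
        out = model(Tensor(img.transpose(2, 0, 1)[None]))
        logits, boxes = out["decoder"][-1]
        probs = 1.0 / (1.0 + np.exp(-logits.data[0]))
        cls = probs.argmax(-1)
        score = probs.max(-1)
        keep = score >= score_threshold
        b = boxes.data[0][keep] * size
        xyxy = _cxcywh_to_xyxy(b)
        xyxy[:, [0, 2]] = (xyxy[:, [0, 2]] - px) / s
        xyxy[:, [1, 3]] = (xyxy[:, [1, 3]] - py) / s
        h, w = image.shape[:2]
        xyxy[:, [0, 2]] = np.clip(xyxy[:, [0, 2]], 0, w)
        xyxy[:, [1, 3]] = np.clip(xyxy[:, [1, 3]], 0, h)
        results.append(DetectionSet(boxes=xyxy, scores=score[keep],
                                    class_ids=cls[keep], image_id=idx))
    return results
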