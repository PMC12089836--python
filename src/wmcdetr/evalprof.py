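"""Detection metrics (precision/recall/AP/mAP/F1/FPS) and the architecture
profiler (parameter count, analytic FLOPs, serialized size).

Metric conventions: greedy score-ranked matching against ground truth at an
IoU threshold; 101-point interpolated average precision; zero denominators
return 0.  FLOP convention: 2 x multiply-accumulates per conv/linear/
attention matmul (bias adds included); normalisation, activations, pooling
and interpolation count zero.  Reported GFLOPs therefore follow the common
"2xMAC" profiler convention, stated here because conventions differ by 2x.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nnkit as nn
from .errors import ArgumentError, ProfilingError
from .detector import DetectionSet, save_checkpoint

IOU_GRID = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


# ---------------------------------------------------------------------------
# matching and PR machinery
# ---------------------------------------------------------------------------

def _iou_xyxy(a, b):
    iw = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    ih = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = iw * ih
    union = ((a[2] - a[0]) * (a[3] - a[1])
             + (b[2] - b[0]) * (b[3] - b[1]) - inter)
    return inter / union if union > 0 else 0.0


@dataclass
class PRCurve:
    """Ranked detection outcomes for one class at one IoU threshold."""

    scores: np.ndarray          # sorted descending
    is_tp: np.ndarray           # bool per ranked detection
    n_gt: int

    @property
    def precision(self):
        tp = np.cumsum(self.is_tp)
        fp = np.cumsum(~self.is_tp)
        return tp / np.maximum(tp + fp, 1)

    @property
    def recall(self):
        if self.n_gt == 0:
            return np.zeros(len(self.is_tp))
        return np.cumsum(self.is_tp) / self.n_gt


def match_detections(preds, gts, iou_threshold=0.5, num_classes=2):
    """Greedy matching of detections to ground truth, per class.

    preds: list of DetectionSet (one per image); gts: list of lists of
    BoxAnnotation.  Each detection (descending score) matches the
    highest-IoU unmatched gt of its class with IoU >= threshold -> TP,
    otherwise FP; unmatched gts are FN.  Returns {class_id: PRCurve}.
    """
    per_class = {c: {"scores": [], "tp": []} for c in range(num_classes)}
    n_gt = {c: 0 for c in range(num_classes)}
    for det, gt in zip(preds, gts):
        gt_by_class = {}
        for g in gt:
            gt_by_class.setdefault(g.class_id, []).append(g.as_tuple())
            n_gt[g.class_id] += 1
        used = {c: np.zeros(len(v), dtype=bool) for c, v in gt_by_class.items()}
        order = np.argsort(-det.scores)
        for i in order:
            c = int(det.class_ids[i])
            box = det.boxes[i]
            cands = gt_by_class.get(c, [])
            best, best_iou = -1, iou_threshold
            for j, gb in enumerate(cands):
                if used[c][j]:
                    continue
                v = _iou_xyxy(box, gb)
                if v >= best_iou:
                    best, best_iou = j, v
            tp = best >= 0
            if tp:
                used[c][best] = True
            per_class[c]["scores"].append(det.scores[i])
            per_class[c]["tp"].append(tp)
    curves = {}
    for c in range(num_classes):
        s = np.asarray(per_class[c]["scores"], dtype=float)
        t = np.asarray(per_class[c]["tp"], dtype=bool)
        order = np.argsort(-s)
        curves[c] = PRCurve(s[order], t[order], n_gt[c])
    return curves


def precision(tp, fp):
    if tp < 0 or fp < 0:
        raise ArgumentError("counts must be non-negative")
    return tp / (tp + fp) if tp + fp else 0.0


def recall(tp, fn):
    if tp < 0 or fn < 0:
        raise ArgumentError("counts must be non-negative")
    return tp / (tp + fn) if tp + fn else 0.0


def f1(p, r):
    return 2 * p * r / (p + r) if p + r else 0.0


def average_precision(curve: PRCurve, convention="101point"):
    """Area under the precision envelope (101-point interpolation)."""
    if curve.n_gt == 0:
        return None
    if len(curve.is_tp) == 0:
        return 0.0
    rec = curve.recall
    prec = curve.precision
    if convention != "101point":
        raise ArgumentError(f"unknown AP convention {convention!r}")
    ap = 0.0
    for r in np.linspace(0, 1, 101):
        mask = rec >= r - 1e-12
        ap += prec[mask].max() if mask.any() else 0.0
    return ap / 101.0


def mean_ap(aps):
    vals = [a for a in aps if a is not None]
    return float(np.mean(vals)) if vals else 0.0


def evaluate_detections(preds, gts, num_classes=2, iou=0.5):
    """Full report: P, R, F1 at the given IoU plus mAP50 and mAP50:95."""
    report = {}
    ap50 = []
    for c, curve in match_detections(preds, gts, 0.5, num_classes).items():
        ap50.append(average_precision(curve))
    report["mAP50"] = mean_ap(ap50)
    ap_all = []
    for thr in IOU_GRID:
        curves = match_detections(preds, gts, float(thr), num_classes)
        ap_all.append(mean_ap([average_precision(c) for c in curves.values()]))
    report["mAP50_95"] = float(np.mean(ap_all))
    curves = match_detections(preds, gts, iou, num_classes)
    tp = sum(int(c.is_tp.sum()) for c in curves.values())
    fp = sum(int((~c.is_tp).sum()) for c in curves.values())
    fn = sum(c.n_gt for c in curves.values()) - tp
    report["precision"] = precision(tp, fp)
    report["recall"] = recall(tp, fn)
    report["f1"] = f1(report["precision"], report["recall"])
    return report


def fps(timings):
    """Frames per second: 1 / arithmetic mean inference time (informational
    only; hardware-dependent)."""
    if len(timings) == 0:
        raise ArgumentError("fps needs at least one timing")
    t = np.asarray(timings, dtype=float)
    if (t <= 0).any():
        raise ArgumentError("timings must be positive")
    return 1.0 / t.mean()


# ---------------------------------------------------------------------------
# architecture profiler
# ---------------------------------------------------------------------------

@dataclass
class ModelProfile:
    params: int
    flops: int
    size_bytes: int
    input_size: int
    breakdown: dict = field(default_factory=dict)

    @property
    def params_m(self):
        return round(self.params / 1e6, 2)

    @property
    def gflops(self):
        return round(self.flops / 1e9, 1)

    @property
    def size_mb(self):
        return round(self.size_bytes / 1e6, 1)

    def report(self):
        return {"params_m": self.params_m, "gflops": self.gflops,
                "size_mb": self.size_mb, "input_size": self.input_size,
                "breakdown": self.breakdown}


def profile_model(model, input_size=640) -> ModelProfile:
    """Profile by meta-execution: the full forward graph runs with
    shape-only tensors, and every matmul-shaped primitive adds its
    2xMAC cost to a global counter.  WTConv layers add their transform
    cost through the printed decomposition/reconstruction formulas."""
    model.eval()
    params = model.num_parameters()
    nn.reset_flops()
    model(nn.meta((1, 3, input_size, input_size)))
    flops = nn.get_flops()
    with tempfile.TemporaryDirectory() as td:
        path = Path(td) / "ckpt.npz"
        save_checkpoint(model, path, half=True)
        size_bytes = path.stat().st_size
    breakdown = {}
    for name in ("backbone", "encoder", "decoder"):
        sub = getattr(model, name, None)
        if sub is not None:
            breakdown[name] = {"params": sub.num_parameters()}
    return ModelProfile(params, flops, size_bytes, input_size, breakdown)


# -- independent per-module counter (cross-check) ---------------------------

def _conv_flops_from_shapes(mod, out_shape):
    n, cout, ho, wo = out_shape
    kh, kw = mod.kernel
    macs = kh * kw * (mod.cin // mod.groups) * cout * ho * wo * n
    return 2 * macs + (n * cout * ho * wo if mod.bias is not None else 0)


def _linear_flops_from_shapes(mod, out_shape):
    tokens = int(np.prod(out_shape[:-1]))
    return 2 * tokens * mod.cin * mod.cout + (tokens * mod.cout
                                              if mod.bias is not None else 0)


def independent_flops(model, input_size=640):
    """Hook-based counter: records every leaf Conv2d/Linear call's output
    shape during a meta forward, then prices each from closed-form layer
    formulas; attention token-mixing and WTConv transforms are priced from
    the recorded shapes of their projection layers.  Independent of the
    op-level accounting in the autodiff kit."""
    from .m2sa import M2SA, MultiHeadAttention
    from .wavelet import WTConv2d, flops_iwt, flops_wt
    from .detector import MSDeformableAttention

    records = []
    hooks_installed = []

    def conv_hook(mod, args, out):
        records.append(("conv", mod, out.shape))

    def linear_hook(mod, args, out):
        records.append(("linear", mod, out.shape))

    def attn_hook(mod, args, out):
        if isinstance(mod, MultiHeadAttention):
            q, k = args[0], args[1]
            records.append(("attn", None, (q.shape[0], q.shape[1], k.shape[1],
                                           mod.dim)))
        elif isinstance(mod, M2SA):
            x = args[0]
            l = x.shape[2] * x.shape[3]
            records.append(("attn", None, (x.shape[0], l, l, mod.cfg.hidden)))
        elif isinstance(mod, MSDeformableAttention):
            pass  # gather-only mixing; projections counted as Linear
        elif isinstance(mod, WTConv2d):
            n, c, h, w = args[0].shape
            lv = mod.cfg.levels
            records.append(("wt", None, n * (flops_wt(c, h, w, lv)
                                             + flops_iwt(c, h, w, lv))))

    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv2d):
            hooks_installed.append((mod, mod.register_forward_hook(conv_hook)))
        elif isinstance(mod, nn.Linear):
            hooks_installed.append((mod, mod.register_forward_hook(linear_hook)))
        elif isinstance(mod, (MultiHeadAttention, M2SA, MSDeformableAttention,
                              WTConv2d)):
            hooks_installed.append((mod, mod.register_forward_hook(attn_hook)))

    model.eval()
    try:
        model(nn.meta((1, 3, input_size, input_size)))
    finally:
        for mod, h in hooks_installed:
            mod._fwd_hooks.remove(h)

    total = 0
    for kind, mod, info in records:
        if kind == "conv":
            total += _conv_flops_from_shapes(mod, info)
        elif kind == "linear":
            total += _linear_flops_from_shapes(mod, info)
        elif kind == "attn":
            n, lq, lk, d = info
            total += 2 * n * (lq * lk * d * 2)     # QK^T and AV matmuls
        elif kind == "wt":
            total += info
    return total


def profiling_sanity(model, input_size=640, tol=0.01):
    """Relative disagreement between the meta-execution profiler and the
    hook-based counter; raises if a layer kind was missed entirely."""
    p = profile_model(model, input_size)
    ind = independent_flops(model, input_size)
    if ind == 0:
        raise ProfilingError("independent counter saw no layers")
    return abs(p.flops - ind) / p.flops
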