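"""Synthetic annotated tea-canopy images, augmentation and dataset splitting.

The generator emulates the two target classes of the field study this
package models: "tea leaf blight" (irregular brown lesions on green leaf
texture, each at least 2% of the image area) and "green mirid bug" (small
elongated dark blobs, at most 1% of the image area), with dense and sparse
layouts and deliberate object overlap.  It is a stand-in with controlled
statistics, not a photorealistic renderer.

Augmentation mirrors the study's procedure — horizontal/vertical flips,
right-angle rotations and Gaussian noise — expanding each source image into
``factor`` variants (default 8), and the split keeps all variants of one
source image in the same subset so no augmented copy leaks across splits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .errors import ArgumentError, ParseError

CLASS_NAMES = ("tea leaf blight", "green mirid bug")

#: augmentation menu, in expansion order (factor n takes the first n)
AUGMENT_MENU = ("original", "fliplr", "flipud", "rot90", "rot180", "rot270",
                "gauss", "fliplr+gauss")


@dataclass
class BoxAnnotation:
    """Axis-aligned box in 0-based half-open pixel coordinates [x1, x2) x [y1, y2)."""

    x1: float
    y1: float
    x2: float
    y2: float
    class_id: int

    def validate(self, width, height):
        ok = 0 <= self.x1 < self.x2 <= width and 0 <= self.y1 < self.y2 <= height
        if not ok:
            raise ArgumentError(f"box {self} out of bounds for {width}x{height}")

    def as_tuple(self):
        return (self.x1, self.y1, self.x2, self.y2)


@dataclass
class SampleRecord:
    image: np.ndarray            # H x W x 3 uint8
    boxes: list
    split: str = "train"
    provenance: str = "original"
    source_id: int = 0

    @property
    def size(self):
        return self.image.shape[1], self.image.shape[0]   # (W, H)


@dataclass
class DatasetManifest:
    records: list
    class_names: tuple = CLASS_NAMES
    counts: dict = field(default_factory=dict)

    def split_records(self, split):
        return [r for r in self.records if r.split == split]

    def equals(self, other, tol=1e-2):
        if len(self.records) != len(other.records):
            return False
        if tuple(self.class_names) != tuple(other.class_names):
            return False
        for a, b in zip(self.records, other.records):
            if a.split != b.split or len(a.boxes) != len(b.boxes):
                return False
            if a.image.shape != b.image.shape or not np.array_equal(a.image, b.image):
                return False
            for ba, bb in zip(a.boxes, b.boxes):
                if ba.class_id != bb.class_id:
                    return False
                if max(abs(p - q) for p, q in zip(ba.as_tuple(), bb.as_tuple())) > tol:
                    return False
        return True


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _leaf_background(rng, size):
    """Green canopy texture: smooth low-frequency mottling + pixel grain."""
    base = np.array([58, 112, 48], dtype=np.float32)
    coarse = rng.normal(0, 1, size=(size // 8 + 1, size // 8 + 1, 3))
    idx = np.linspace(0, coarse.shape[0] - 1, size)
    xi = idx.astype(int)
    coarse_up = coarse[xi][:, xi]
    grain = rng.normal(0, 6, size=(size, size, 3))
    img = base + 22 * coarse_up + grain
    return np.clip(img, 0, 255).astype(np.uint8)


def _blob_polygon(rng, cx, cy, rx, ry, angle, wobble):
    """Closed polygon: ellipse with multiplicative radial perturbation."""
    k = 24
    theta = np.linspace(0, 2 * math.pi, k, endpoint=False)
    harm = (wobble * rng.normal(size=3)[:, None]
            * np.sin(np.arange(2, 5)[:, None] * theta + rng.uniform(0, 6.28, size=(3, 1))))
    r_mod = np.clip(1.0 + harm.sum(axis=0), 0.8, 1.25)
    ex = rx * r_mod * np.cos(theta)
    ey = ry * r_mod * np.sin(theta)
    ca, sa = math.cos(angle), math.sin(angle)
    px = cx + ca * ex - sa * ey
    py = cy + sa * ex + ca * ey
    return list(zip(px.tolist(), py.tolist()))


def _render_object(rng, img, class_id, size, center=None):
    """Draw one object; returns its BoxAnnotation (from the rendered mask)."""
    margin = int(0.18 * size)
    if center is None:
        cx = rng.uniform(margin, size - margin)
        cy = rng.uniform(margin, size - margin)
    else:
        cx, cy = center
    if class_id == 0:   # blight lesion: irregular brown blob, >= 2% area
        rx = rng.uniform(0.10, 0.16) * size
        ry = rng.uniform(0.10, 0.16) * size
        colour = tuple(int(c) for c in
                       np.clip([120 + rng.normal(0, 12), 72 + rng.normal(0, 8),
                                30 + rng.normal(0, 6)], 0, 255))
        poly = _blob_polygon(rng, cx, cy, rx, ry, rng.uniform(0, math.pi), wobble=0.10)
    else:               # mirid bug: small elongated dark blob, <= 1% area
        rx = rng.uniform(0.040, 0.060) * size
        ry = rng.uniform(0.010, 0.016) * size
        colour = tuple(int(c) for c in
                       np.clip([26 + rng.normal(0, 5), 40 + rng.normal(0, 6),
                                22 + rng.normal(0, 4)], 0, 255))
        poly = _blob_polygon(rng, cx, cy, rx, ry, rng.uniform(0, math.pi), wobble=0.05)

    mask_im = Image.new("1", (size, size), 0)
    ImageDraw.Draw(mask_im).polygon(poly, fill=1)
    mask = np.asarray(mask_im, dtype=bool)
    if class_id == 0 and center is None:
        # lesions must cover >= 2% of the image; retry if edge-clipped
        for _ in range(10):
            if mask.sum() >= 0.02 * size * size:
                break
            cx = rng.uniform(margin, size - margin)
            cy = rng.uniform(margin, size - margin)
            rx = rng.uniform(0.11, 0.16) * size
            ry = rng.uniform(0.11, 0.16) * size
            poly = _blob_polygon(rng, cx, cy, rx, ry, rng.uniform(0, math.pi),
                                 wobble=0.08)
            mask_im = Image.new("1", (size, size), 0)
            ImageDraw.Draw(mask_im).polygon(poly, fill=1)
            mask = np.asarray(mask_im, dtype=bool)
    if not mask.any():
        return None
    img[mask] = colour
    ys, xs = np.nonzero(mask)
    return BoxAnnotation(float(xs.min()), float(ys.min()),
                         float(xs.max() + 1), float(ys.max() + 1), class_id)


def generate_base_images(n, size=640, seed=0, class_mix=0.5, max_objects=12):
    """Generate ``n`` synthetic annotated records.

    class_mix: probability that an object is class 0 (blight).  Each image
    holds 1..max_objects objects; at least half the multi-object images get
    a deliberately overlapping pair.  Same seed -> byte-identical output.
    """
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    if size < 64:
        raise ArgumentError(f"size must be >= 64, got {size}")
    if max_objects < 1:
        raise ArgumentError("max_objects must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        img = _leaf_background(rng, size)
        k = int(rng.integers(1, max_objects + 1))
        force_overlap = k >= 2 and rng.random() < 0.5
        boxes = []
        for j in range(k):
            cid = 0 if rng.random() < class_mix else 1
            center = None
            if force_overlap and j == 1 and boxes:
                b0 = boxes[0]
                center = ((b0.x1 + b0.x2) / 2 + rng.normal(0, 0.03 * size),
                          (b0.y1 + b0.y2) / 2 + rng.normal(0, 0.03 * size))
                center = (float(np.clip(center[0], 4, size - 4)),
                          float(np.clip(center[1], 4, size - 4)))
            box = _render_object(rng, img, cid, size, center)
            if box is not None:
                boxes.append(box)
        for b in boxes:
            b.validate(size, size)
        records.append(SampleRecord(img, boxes, source_id=i))
    return records


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _tf_box(box, variant, w, h):
    x1, y1, x2, y2 = box.as_tuple()
    if variant == "fliplr":
        t = (w - x2, y1, w - x1, y2)
    elif variant == "flipud":
        t = (x1, h - y2, x2, h - y1)
    elif variant == "rot90":      # counter-clockwise: (x, y) -> (y, W - x)
        t = (y1, w - x2, y2, w - x1)
    elif variant == "rot180":
        t = (w - x2, h - y2, w - x1, h - y1)
    elif variant == "rot270":     # clockwise: (x, y) -> (H - y, x)
        t = (h - y2, x1, h - y1, x2)
    else:
        t = (x1, y1, x2, y2)
    return BoxAnnotation(*t, class_id=box.class_id)


def _tf_image(img, variant):
    if variant == "fliplr":
        return np.fliplr(img).copy()
    if variant == "flipud":
        return np.flipud(img).copy()
    if variant == "rot90":
        return np.rot90(img, 1).copy()
    if variant == "rot180":
        return np.rot90(img, 2).copy()
    if variant == "rot270":
        return np.rot90(img, 3).copy()
    return img.copy()


def transform_record(rec, variant, noise_sigma=10.0, rng=None):
    """Apply one augmentation variant; geometric parts move the boxes, the
    Gaussian-noise part leaves them untouched."""
    parts = variant.split("+")
    img = rec.image
    boxes = rec.boxes
    for part in parts:
        if part in ("original", "gauss"):
            img = img.copy()
        else:
            w, h = img.shape[1], img.shape[0]
            boxes = [_tf_box(b, part, w, h) for b in boxes]
            img = _tf_image(img, part)
        if part == "gauss":
            noise = rng.normal(0, noise_sigma, size=img.shape)
            img = np.clip(img.astype(np.float32) + noise, 0, 255).astype(np.uint8)
    boxes = [BoxAnnotation(*b.as_tuple(), class_id=b.class_id) for b in boxes]
    return SampleRecord(img, boxes, split=rec.split, provenance=variant,
                        source_id=rec.source_id)


def augment_expand(records, factor=8, noise_sigma=10.0, seed=0):
    """Expand each record into ``factor`` variants from the fixed menu."""
    if factor < 1:
        raise ArgumentError("factor must be >= 1")
    if factor > len(AUGMENT_MENU):
        raise ArgumentError(
            f"factor {factor} exceeds the {len(AUGMENT_MENU)}-variant menu")
    rng = np.random.default_rng(seed)
    out = []
    for rec in records:
        for variant in AUGMENT_MENU[:factor]:
            out.append(transform_record(rec, variant, noise_sigma, rng))
    return out


def rotate_arbitrary(rec, angle_deg):
    """Arbitrary-angle rotation with box re-fitting (axis-aligned hull of the
    rotated corners).  Boxes are approximate for non-right angles, so this
    variant sits outside the exact-invariant augmentation menu."""
    from scipy.ndimage import rotate as nd_rotate
    img = nd_rotate(rec.image, angle_deg, reshape=False, order=1, mode="reflect")
    h, w = rec.image.shape[:2]
    cx, cy = w / 2, h / 2
    a = math.radians(-angle_deg)   # image rotation is ccw for positive angle
    ca, sa = math.cos(a), math.sin(a)
    boxes = []
    for b in rec.boxes:
        corners = np.array([[b.x1, b.y1], [b.x2, b.y1], [b.x1, b.y2], [b.x2, b.y2]])
        rel = corners - [cx, cy]
        rot = rel @ np.array([[ca, sa], [-sa, ca]]) + [cx, cy]
        x1, y1 = np.clip(rot.min(axis=0), 0, [w, h])
        x2, y2 = np.clip(rot.max(axis=0), 0, [w, h])
        if x2 > x1 and y2 > y1:
            boxes.append(BoxAnnotation(float(x1), float(y1), float(x2), float(y2),
                                       b.class_id))
    return SampleRecord(img.astype(np.uint8), boxes, split=rec.split,
                        provenance=f"rot{angle_deg:g}", source_id=rec.source_id)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(records, ratios=(0.7, 0.2, 0.1), seed=0):
    """Assign records to train/val/test, grouped by source image.

    With 160 sources expanded x8 and the default ratios this yields exactly
    896/256/128 records (112/32/16 sources).
    """
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ArgumentError(f"split ratios must sum to 1, got {ratios}")
    sources = sorted({r.source_id for r in records})
    rng = np.random.default_rng(seed)
    order = [sources[i] for i in rng.permutation(len(sources))]
    ns = len(sources)
    n_val = int(round(ns * ratios[1]))
    n_test = int(round(ns * ratios[2]))
    n_train = ns - n_val - n_test
    assign = {}
    for i, src in enumerate(order):
        if i < n_train:
            assign[src] = "train"
        elif i < n_train + n_val:
            assign[src] = "val"
        else:
            assign[src] = "test"
    out = []
    for r in records:
        out.append(SampleRecord(r.image, r.boxes, split=assign[r.source_id],
                                provenance=r.provenance, source_id=r.source_id))
    counts = {s: sum(1 for r in out if r.split == s) for s in ("train", "val", "test")}
    return DatasetManifest(records=out, class_names=CLASS_NAMES, counts=counts)


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------

def _record_stem(rec, idx):
    prov = rec.provenance.replace("+", "-")
    return f"img{rec.source_id:05d}_{idx:05d}_{prov}_{rec.split}"


def write_annotations(manifest, fmt, path):
    """Write images + annotations as a YOLO-txt or COCO-JSON file tree."""
    path = Path(path)
    if fmt == "yolo-txt":
        for sub in ("images", "labels"):
            (path / sub).mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(manifest.records):
            stem = _record_stem(rec, i)
            Image.fromarray(rec.image).save(path / "images" / f"{stem}.png")
            w, h = rec.size
            lines = []
            for b in rec.boxes:
                cx = (b.x1 + b.x2) / 2 / w
                cy = (b.y1 + b.y2) / 2 / h
                bw = (b.x2 - b.x1) / w
                bh = (b.y2 - b.y1) / h
                lines.append(f"{b.class_id} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
            (path / "labels" / f"{stem}.txt").write_text("\n".join(lines) + ("\n" if lines else ""))
        (path / "classes.txt").write_text("\n".join(manifest.class_names) + "\n")
    elif fmt == "coco-json":
        (path / "images").mkdir(parents=True, exist_ok=True)
        images, annotations = [], []
        ann_id = 1
        for i, rec in enumerate(manifest.records):
            stem = _record_stem(rec, i)
            Image.fromarray(rec.image).save(path / "images" / f"{stem}.png")
            w, h = rec.size
            images.append({"id": i + 1, "file_name": f"{stem}.png", "width": w,
                           "height": h, "split": rec.split,
                           "provenance": rec.provenance, "source_id": rec.source_id})
            for b in rec.boxes:
                annotations.append({
                    "id": ann_id, "image_id": i + 1,
                    "category_id": b.class_id + 1,      # COCO ids are 1-based
                    "bbox": [round(b.x1, 2), round(b.y1, 2),
                             round(b.x2 - b.x1, 2), round(b.y2 - b.y1, 2)],
                    "area": round((b.x2 - b.x1) * (b.y2 - b.y1), 2),
                    "iscrowd": 0})
                ann_id += 1
        categories = [{"id": c + 1, "name": name}
                      for c, name in enumerate(manifest.class_names)]
        (path / "annotations.json").write_text(json.dumps(
            {"images": images, "annotations": annotations,
             "categories": categories}, indent=1))
    else:
        raise ArgumentError(f"unknown annotation format {fmt!r}")
    return path


def _parse_stem(stem):
    parts = stem.split("_")
    src = int(parts[0][3:])
    prov = parts[2].replace("-", "+")
    split = parts[3]
    return src, prov, split


def read_annotations(path, fmt):
    path = Path(path)
    if fmt == "yolo-txt":
        records = []
        label_dir = path / "labels"
        for img_file in sorted((path / "images").glob("*.png")):
            img = np.asarray(Image.open(img_file).convert("RGB"))
            h, w = img.shape[:2]
            boxes = []
            txt = label_dir / (img_file.stem + ".txt")
            if txt.exists():
                for ln, line in enumerate(txt.read_text().splitlines(), 1):
                    if not line.strip():
                        continue
                    bits = line.split()
                    if len(bits) != 5:
                        raise ParseError(f"{txt.name} line {ln}: expected "
                                         f"'class cx cy w h', got {line!r}")
                    try:
                        cid = int(bits[0])
                        cx, cy, bw, bh = map(float, bits[1:])
                    except ValueError as e:
                        raise ParseError(f"{txt.name} line {ln}: {e}") from None
                    boxes.append(BoxAnnotation((cx - bw / 2) * w, (cy - bh / 2) * h,
                                               (cx + bw / 2) * w, (cy + bh / 2) * h, cid))
            src, prov, split = _parse_stem(img_file.stem)
            records.append(SampleRecord(img, boxes, split=split, provenance=prov,
                                        source_id=src))
        names_file = path / "classes.txt"
        names = tuple(names_file.read_text().splitlines()) if names_file.exists() \
            else CLASS_NAMES
        counts = {s: sum(1 for r in records if r.split == s)
                  for s in ("train", "val", "test")}
        return DatasetManifest(records, names, counts)
    if fmt == "coco-json":
        ann_path = path / "annotations.json"
        try:
            doc = json.loads(ann_path.read_text())
        except json.JSONDecodeError as e:
            raise ParseError(f"{ann_path.name}: {e}") from None
        for key in ("images", "annotations", "categories"):
            if key not in doc:
                raise ParseError(f"{ann_path.name}: missing top-level key {key!r}")
        by_img = {}
        for ann in doc["annotations"]:
            if "bbox" not in ann or len(ann["bbox"]) != 4:
                raise ParseError(f"{ann_path.name}: annotation id "
                                 f"{ann.get('id')} has malformed bbox")
            x, y, w, h = ann["bbox"]
            by_img.setdefault(ann["image_id"], []).append(
                BoxAnnotation(x, y, x + w, y + h, ann["category_id"] - 1))
        records = []
        for im in doc["images"]:
            img = np.asarray(Image.open(path / "images" / im["file_name"]).convert("RGB"))
            records.append(SampleRecord(
                img, by_img.get(im["id"], []), split=im.get("split", "train"),
                provenance=im.get("provenance", "original"),
                source_id=im.get("source_id", im["id"])))
        names = tuple(c["name"] for c in sorted(doc["categories"], key=lambda c: c["id"]))
        counts = {s: sum(1 for r in records if r.split == s)
                  for s in ("train", "val", "test")}
        return DatasetManifest(records, names, counts)
    raise ArgumentError(f"unknown annotation format {fmt!r}")
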