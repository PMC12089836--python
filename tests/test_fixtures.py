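"""Synthetic dataset generation, augmentation algebra, splitting and IO."""

import numpy as np
import pytest

from wmcdetr.errors import ArgumentError, ParseError
from wmcdetr.fixtures import (AUGMENT_MENU, BoxAnnotation, SampleRecord,
                              augment_expand, generate_base_images,
                              read_annotations, rotate_arbitrary,
                              split_dataset, transform_record,
                              write_annotations)


def iou(a, b):
    ix = max(0.0, min(a.x2, b.x2) - max(a.x1, b.x1))
    iy = max(0.0, min(a.y2, b.y2) - max(a.y1, b.y1))
    inter = ix * iy
    ua = (a.x2 - a.x1) * (a.y2 - a.y1) + (b.x2 - b.x1) * (b.y2 - b.y1) - inter
    return inter / ua if ua else 0.0


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def test_generation_contract():
    recs = generate_base_images(24, size=96, seed=7)
    assert len(recs) == 24
    for r in recs:
        assert r.image.shape == (96, 96, 3) and r.image.dtype == np.uint8
        assert 1 <= len(r.boxes) <= 12
        for b in r.boxes:
            assert 0 <= b.x1 < b.x2 <= 96 and 0 <= b.y1 < b.y2 <= 96
            assert b.class_id in (0, 1)


def test_class_morphology_scales():
    recs = generate_base_images(16, size=128, seed=3, class_mix=0.5)
    area = 128 * 128
    for r in recs:
        for b in r.boxes:
            box_area = (b.x2 - b.x1) * (b.y2 - b.y1)
            if b.class_id == 0:
                # lesion boxes bound a mask covering >= 2% of the image
                assert box_area >= 0.02 * area
            else:
                # bugs are small: even the box stays within ~1.5% of the image
                assert box_area <= 0.015 * area


def test_degenerate_class_mix():
    recs = generate_base_images(1, size=96, seed=1, class_mix=1.0)
    assert all(b.class_id == 0 for b in recs[0].boxes)
    recs = generate_base_images(1, size=96, seed=1, class_mix=0.0)
    assert all(b.class_id == 1 for b in recs[0].boxes)


def test_generation_deterministic():
    a = generate_base_images(10, size=96, seed=7)
    b = generate_base_images(10, size=96, seed=7)
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.image, rb.image)
        assert [x.as_tuple() for x in ra.boxes] == [x.as_tuple() for x in rb.boxes]


def test_generation_argument_errors():
    with pytest.raises(ArgumentError):
        generate_base_images(0, size=96)
    with pytest.raises(ArgumentError):
        generate_base_images(4, size=32)


def test_overlap_rate_among_multi_object_images():
    recs = generate_base_images(40, size=96, seed=11)
    multi = [r for r in recs if len(r.boxes) >= 2]
    assert multi, "expected some multi-object images"
    overlapping = 0
    for r in multi:
        if any(iou(a, b) > 0 for i, a in enumerate(r.boxes)
               for b in r.boxes[i + 1:]):
            overlapping += 1
    assert overlapping / len(multi) >= 0.2


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _dummy_record(w=640, h=640, boxes=None):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    boxes = boxes or [BoxAnnotation(10, 20, 50, 60, 0)]
    return SampleRecord(img, boxes, source_id=0)


def test_fliplr_box_formula():
    rec = transform_record(_dummy_record(), "fliplr")
    assert rec.boxes[0].as_tuple() == (590, 20, 630, 60)


def test_rot90_box_formula():
    rec = transform_record(_dummy_record(), "rot90")
    assert rec.boxes[0].as_tuple() == (20, 590, 60, 630)


def test_expansion_factor_and_provenance():
    base = generate_base_images(5, size=96, seed=2)
    out = augment_expand(base, factor=8, seed=0)
    assert len(out) == 40
    assert [r.provenance for r in out[:8]] == list(AUGMENT_MENU)
    with pytest.raises(ArgumentError):
        augment_expand(base, factor=9)


def test_gaussian_noise_preserves_boxes():
    base = generate_base_images(2, size=96, seed=2)
    out = augment_expand(base, factor=8, seed=0)
    for src, gauss in zip(out[::8], out[6::8]):
        assert gauss.provenance == "gauss"
        assert [b.as_tuple() for b in gauss.boxes] == [b.as_tuple() for b in src.boxes]
        assert not np.array_equal(gauss.image, src.image)


@pytest.mark.parametrize("variant,times", [("fliplr", 2), ("flipud", 2), ("rot90", 4)])
def test_augmentation_group_property(variant, times):
    rec = generate_base_images(1, size=96, seed=5)[0]
    cur = rec
    for _ in range(times):
        cur = transform_record(cur, variant)
    assert np.array_equal(cur.image, rec.image)
    got = [tuple(round(v, 6) for v in b.as_tuple()) for b in cur.boxes]
    want = [tuple(round(v, 6) for v in b.as_tuple()) for b in rec.boxes]
    assert got == want


@pytest.mark.parametrize("variant", ["fliplr", "flipud", "rot90", "rot180", "rot270"])
def test_box_mask_consistency(variant):
    # transforming a rendered box mask == rendering the transformed boxes
    rec = generate_base_images(1, size=96, seed=9)[0]

    def render(boxes, h, w):
        m = np.zeros((h, w), dtype=bool)
        for b in boxes:
            m[int(b.y1):int(b.y2), int(b.x1):int(b.x2)] = True
        return m

    out = transform_record(rec, variant)
    mask0 = render(rec.boxes, *rec.image.shape[:2])
    from wmcdetr.fixtures import _tf_image
    mask_t = _tf_image(mask0[..., None], variant)[..., 0].astype(bool)
    mask_boxes = render(out.boxes, *out.image.shape[:2])
    assert np.array_equal(mask_t, mask_boxes)


def test_arbitrary_rotation_flag():
    rec = generate_base_images(1, size=96, seed=4)[0]
    out = rotate_arbitrary(rec, 30.0)
    assert out.image.shape == rec.image.shape
    assert out.provenance == "rot30"
    for b in out.boxes:
        assert 0 <= b.x1 < b.x2 <= 96 and 0 <= b.y1 < b.y2 <= 96


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_counts_and_leakage():
    base = generate_base_images(20, size=96, seed=1)
    full = augment_expand(base, factor=8, seed=0)
    man = split_dataset(full, seed=0)
    assert man.counts == {"train": 112, "val": 32, "test": 16}
    by_split = {s: {r.source_id for r in man.records if r.split == s}
                for s in ("train", "val", "test")}
    assert not (by_split["train"] & by_split["val"])
    assert not (by_split["train"] & by_split["test"])
    assert not (by_split["val"] & by_split["test"])
    # all variants of one source share a split
    for src in {r.source_id for r in man.records}:
        splits = {r.split for r in man.records if r.source_id == src}
        assert len(splits) == 1


def test_split_single_source_stays_together():
    base = generate_base_images(1, size=96, seed=1)
    full = augment_expand(base, factor=8, seed=0)
    man = split_dataset(full, seed=3)
    assert len({r.split for r in man.records}) == 1


def test_split_deterministic_and_ratio_error():
    base = generate_base_images(6, size=96, seed=1)
    full = augment_expand(base, factor=4, seed=0)
    m1 = split_dataset(full, seed=5)
    m2 = split_dataset(full, seed=5)
    assert [r.split for r in m1.records] == [r.split for r in m2.records]
    with pytest.raises(ArgumentError):
        split_dataset(full, ratios=(0.5, 0.2, 0.2))


# ---------------------------------------------------------------------------
# annotation IO
# ---------------------------------------------------------------------------

def _small_manifest(n=10):
    base = generate_base_images(n, size=96, seed=8)
    return split_dataset(base, seed=0)


def test_yolo_line_normalisation(tmp_path):
    img = np.zeros((640, 640, 3), dtype=np.uint8)
    rec = SampleRecord(img, [BoxAnnotation(0, 0, 320, 320, 0)], split="train")
    from wmcdetr.fixtures import DatasetManifest
    man = DatasetManifest([rec], counts={"train": 1, "val": 0, "test": 0})
    write_annotations(man, "yolo-txt", tmp_path)
    txt = next((tmp_path / "labels").glob("*.txt")).read_text().strip()
    assert txt == "0 0.250000 0.250000 0.500000 0.500000"


@pytest.mark.parametrize("fmt", ["yolo-txt", "coco-json"])
def test_roundtrip(tmp_path, fmt):
    man = _small_manifest(10)
    write_annotations(man, fmt, tmp_path / fmt)
    back = read_annotations(tmp_path / fmt, fmt)
    assert man.equals(back)


def test_unknown_format_errors(tmp_path):
    man = _small_manifest(1)
    with pytest.raises(ArgumentError):
        write_annotations(man, "voc-xml", tmp_path)
    with pytest.raises(ArgumentError):
        read_annotations(tmp_path, "voc-xml")


def test_malformed_yolo_names_line(tmp_path):
    man = _small_manifest(1)
    write_annotations(man, "yolo-txt", tmp_path)
    txt = next((tmp_path / "labels").glob("*.txt"))
    txt.write_text("0 0.5 0.5 0.1\n")
    with pytest.raises(ParseError, match="line 1"):
        read_annotations(tmp_path, "yolo-txt")


def test_malformed_coco_names_record(tmp_path):
    man = _small_manifest(1)
    write_annotations(man, "coco-json", tmp_path)
    import json
    doc = json.loads((tmp_path / "annotations.json").read_text())
    doc["annotations"][0]["bbox"] = [1, 2, 3]
    (tmp_path / "annotations.json").write_text(json.dumps(doc))
    with pytest.raises(ParseError, match="bbox"):
        read_annotations(tmp_path, "coco-json")
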