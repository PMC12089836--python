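"""Detector assembly: GIoU, Hungarian matching, contracts, training loop."""

import itertools

import numpy as np
import pytest

from wmcdetr.detector import (CCFF, DetectionSet, ModelConfig, TrainConfig,
                              build_model, giou, hungarian_assign,
                              hungarian_match, letterbox, load_checkpoint,
                              predict, save_checkpoint, train)
from wmcdetr.errors import ArgumentError, ConfigError
from wmcdetr.fixtures import generate_base_images
from wmcdetr.nnkit import Tensor

RNG = np.random.default_rng(21)


# ---------------------------------------------------------------------------
# GIoU
# ---------------------------------------------------------------------------

def test_giou_identical_boxes():
    assert giou((0, 0, 10, 10), (0, 0, 10, 10)) == pytest.approx(1.0)


def test_giou_touching_boxes():
    # touching: IoU 0, hull == union -> GIoU 0
    assert giou((0, 0, 10, 10), (10, 0, 20, 10)) == pytest.approx(0.0)


def test_giou_distant_boxes():
    # opposite corners of a 100x100 hull: 0 - (10000-200)/10000
    assert giou((0, 0, 10, 10), (90, 90, 100, 100)) == pytest.approx(-0.98)


def test_giou_symmetric_and_bounded():
    for _ in range(20):
        # +[0, 1] staggers the two coordinates so x1 < x2 strictly
        ax = sorted(RNG.uniform(0, 50, 2) + [0, 1])
        ay = sorted(RNG.uniform(0, 50, 2) + [0, 1])
        bx = sorted(RNG.uniform(0, 50, 2) + [0, 1])
        by = sorted(RNG.uniform(0, 50, 2) + [0, 1])
        a = (ax[0], ay[0], ax[1], ay[1])
        b = (bx[0], by[0], bx[1], by[1])
        g1, g2 = giou(a, b), giou(b, a)
        assert g1 == pytest.approx(g2, abs=1e-9)
        assert -1 < g1 <= 1


def test_giou_degenerate_box_rejected():
    with pytest.raises(ArgumentError):
        giou((0, 0, 0, 10), (0, 0, 10, 10))


# ---------------------------------------------------------------------------
# Hungarian matching
# ---------------------------------------------------------------------------

def test_identity_assignment_for_exact_duplicates():
    gt_boxes = np.array([[0.2, 0.2, 0.1, 0.1], [0.7, 0.7, 0.1, 0.1]], np.float32)
    probs = np.array([[0.9, 0.1], [0.1, 0.9]], np.float32)
    pi, gi = hungarian_match(gt_boxes, probs, gt_boxes, np.array([0, 1]))
    assert dict(zip(pi, gi)) == {0: 0, 1: 1}


def test_empty_gt_gives_empty_assignment():
    pi, gi = hungarian_match(np.zeros((3, 4), np.float32),
                             np.zeros((3, 2), np.float32),
                             np.zeros((0, 4), np.float32), np.zeros(0, int))
    assert len(pi) == 0 and len(gi) == 0


def test_hand_built_cost_matrix_against_bruteforce():
    cost = np.array([[1.0, 9.0], [9.0, 1.0], [5.0, 5.0]])
    pi, gi = hungarian_assign(cost)
    got = cost[pi, gi].sum()
    # brute force: all one-to-one assignments of the 2 gts to 3 preds
    best = min(sum(cost[p, g] for g, p in enumerate(perm))
               for perm in itertools.permutations(range(3), 2))
    assert got == pytest.approx(best) == pytest.approx(2.0)
    assert dict(zip(pi, gi)) == {0: 0, 1: 1}


# ---------------------------------------------------------------------------
# model contracts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_baseline():
    # 192px input keeps >= 300 encoder tokens so the full query budget exists
    return build_model(ModelConfig(variant="baseline", input_size=192), seed=0)


@pytest.fixture(scope="module")
def tiny_full():
    return build_model(ModelConfig(variant="full", input_size=64), seed=0)


def test_forward_contract_scores_and_count(small_baseline):
    m = small_baseline
    x = Tensor(RNG.random((1, 3, 192, 192)).astype(np.float32))
    out = m(x)
    logits, boxes = out["decoder"][-1]
    assert logits.shape == (1, 300, 2)
    assert boxes.shape == (1, 300, 4)
    probs = 1 / (1 + np.exp(-logits.numpy()))
    assert (probs >= 0).all() and (probs <= 1).all()
    assert (boxes.numpy() >= 0).all() and (boxes.numpy() <= 1).all()


def test_eval_forward_deterministic(tiny_full):
    m = tiny_full
    m.eval()
    x = Tensor(RNG.random((1, 3, 64, 64)).astype(np.float32))
    a = m(x)["decoder"][-1][1].numpy()
    b = m(x)["decoder"][-1][1].numpy()
    assert np.array_equal(a, b)


def test_parameter_ordering_across_ablations():
    params = {v: build_model(v, seed=0).num_parameters()
              for v in ("baseline", "wtconv_only", "csrfpn_only", "full")}
    assert params["full"] < params["wtconv_only"] < params["baseline"]
    assert params["csrfpn_only"] < params["baseline"]


def test_variant_config_validation():
    with pytest.raises(ConfigError):
        ModelConfig(variant="resnet50")
    from wmcdetr.backbone import BackboneConfig
    with pytest.raises(ConfigError):
        ModelConfig(variant="baseline", backbone=BackboneConfig(policy="second"))


def test_gradient_flows_to_every_component(tiny_full):
    m = build_model(ModelConfig(variant="full", input_size=64), seed=1)
    recs = generate_base_images(2, size=64, seed=2, max_objects=2)
    train(m, recs, TrainConfig(batch_size=2, seed=0), iterations=1)
    # after the step, inspect grads of a fresh backward pass
    from wmcdetr.detector import records_to_batch, detection_loss, build_dn_batch
    m.train()
    imgs, targets = records_to_batch(recs, 64)
    dn = build_dn_batch(targets, m.cfg.dn_queries, 2, np.random.default_rng(0))
    out = m(Tensor(imgs), dn=dn)
    loss, _ = detection_loss(out, targets, 2, out.get("dn_meta"))
    m.zero_grad()
    loss.backward()
    for comp in ("backbone", "encoder", "decoder"):
        sub = getattr(m, comp)
        grads = [p.grad for _, p in sub.named_parameters()]
        nonzero = sum(1 for g in grads if g is not None and np.abs(g).max() > 0)
        assert nonzero / len(grads) > 0.9, f"{comp}: {nonzero}/{len(grads)}"


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def test_predict_thresholds(small_baseline):
    img = (RNG.random((192, 192, 3)) * 255).astype(np.uint8)
    empty = predict(small_baseline, [img], score_threshold=1.0)[0]
    assert len(empty.boxes) == 0
    full = predict(small_baseline, [img], score_threshold=0.0)[0]
    assert len(full.boxes) == 300
    h, w = img.shape[:2]
    assert (full.boxes[:, [0, 2]] >= 0).all() and (full.boxes[:, [0, 2]] <= w).all()
    assert (full.boxes[:, [1, 3]] >= 0).all() and (full.boxes[:, [1, 3]] <= h).all()


def test_predict_letterboxes_odd_sizes(small_baseline):
    img = (RNG.random((100, 60, 3)) * 255).astype(np.uint8)
    out = predict(small_baseline, [img], score_threshold=0.0)[0]
    assert (out.boxes[:, [0, 2]] <= 60).all()
    assert (out.boxes[:, [1, 3]] <= 100).all()


def test_letterbox_geometry():
    img = np.full((100, 50, 3), 200, np.uint8)
    out, s, (px, py) = letterbox(img, 64)
    assert out.shape == (64, 64, 3)
    assert s == pytest.approx(0.64)
    assert px == (64 - 32) // 2 and py == 0


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def test_training_is_seed_deterministic():
    recs = generate_base_images(2, size=64, seed=3, max_objects=2)
    hists = []
    for _ in range(2):
        m = build_model(ModelConfig(variant="full", input_size=64), seed=7)
        res = train(m, recs, TrainConfig(batch_size=2, seed=4), iterations=2)
        hists.append(res["history"])
    assert hists[0] == hists[1]


def test_training_writes_jsonl_log(tmp_path):
    recs = generate_base_images(2, size=64, seed=3, max_objects=2)
    m = build_model(ModelConfig(variant="baseline", input_size=64), seed=0)
    log = tmp_path / "train.jsonl"
    res = train(m, recs, TrainConfig(batch_size=2, seed=0, log_path=str(log)),
                iterations=2)
    assert not res["aborted"]
    import json
    lines = [json.loads(l) for l in log.read_text().splitlines()]
    assert all("epoch" in l for l in lines)


def test_checkpoint_roundtrip(tmp_path, tiny_full):
    m = tiny_full
    path = tmp_path / "ckpt.npz"
    save_checkpoint(m, path)
    m2 = build_model(ModelConfig(variant="full", input_size=64), seed=99)
    load_checkpoint(m2, path)
    x = Tensor(RNG.random((1, 3, 64, 64)).astype(np.float32))
    m.eval(), m2.eval()
    a = m(x)["decoder"][-1][1].numpy()
    b = m2(x)["decoder"][-1][1].numpy()
    assert np.allclose(a, b, atol=1e-6)
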