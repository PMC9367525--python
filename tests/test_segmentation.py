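import numpy as np
import pytest

from camquant import segmentation as seg
from camquant import synthetic as syn
from camquant._nn import UNet


TINY = seg.SegmentationConfig(
    depth=2, base_channels=4, crop_size=64, crops_per_image=2, batch_size=2,
    max_epochs=4, patience=4, tile_size=64, tile_overlap=16, seed=0,
)


def _tiny_sample(seed=5, size=64):
    params = syn.TreeParams(n_roots=2, diameter_range=(3.0, 10.0),
                            deep_fraction=0.0, branch_probability=0.05)
    return syn.make_sample((size, size), params, seed=seed)


# ---------------------------------------------------------------------------
# augment_pair
# ---------------------------------------------------------------------------

def _identity_config():
    return seg.SegmentationConfig(
        flip_lr_prob=0.0, flip_ud_prob=0.0, rotations=(0,),
        color_shift=0.0, spatial_shift=0.0,
    )


def test_augment_identity_case():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, size=(32, 32, 3), dtype=np.uint8)
    mask = rng.random((32, 32)) < 0.3
    out_img, out_mask = seg.augment_pair(img, mask, _identity_config(), rng)
    np.testing.assert_array_equal(out_img, img)
    np.testing.assert_array_equal(out_mask, mask)


def test_augment_flip_involution():
    rng = np.random.default_rng(1)
    mask = np.zeros((16, 16), dtype=bool)
    mask[3:6, 2:5] = True  # off-center
    flipped = mask[:, ::-1]
    np.testing.assert_array_equal(flipped[:, ::-1], mask)
    assert not np.array_equal(flipped, mask)


def test_augment_geometric_transforms_match():
    cfg = seg.SegmentationConfig(color_shift=0.0)
    rng = np.random.default_rng(2)
    img = np.zeros((32, 32, 3), dtype=np.uint8)
    img[:, :, 0] = 255 * (np.arange(32)[:, None] < 16)
    mask = img[:, :, 0] > 0
    for _ in range(20):
        ai, am = seg.augment_pair(img, mask, cfg, rng)
        np.testing.assert_array_equal(ai[:, :, 0] > 0, am)
        assert np.isin(np.unique(am), (False, True)).all()


def test_augment_flip_fraction_binomial():
    # Monte Carlo: with flip prob 0.5 the flipped fraction lands near 0.5
    cfg = seg.SegmentationConfig(
        flip_lr_prob=0.5, flip_ud_prob=0.0, rotations=(0,),
        color_shift=0.0, spatial_shift=0.0,
    )
    rng = np.random.default_rng(3)
    img = np.zeros((8, 8, 3), dtype=np.uint8)
    img[:, 0] = 255
    mask = np.zeros((8, 8), dtype=bool)
    flips = 0
    n = 1000
    for _ in range(n):
        ai, _ = seg.augment_pair(img, mask, cfg, rng)
        if ai[0, -1, 0] == 255:
            flips += 1
    assert 0.45 <= flips / n <= 0.55


def test_augment_color_shift_image_only():
    cfg = seg.SegmentationConfig(
        flip_lr_prob=0.0, flip_ud_prob=0.0, rotations=(0,),
        color_shift=20.0, spatial_shift=0.0,
    )
    rng = np.random.default_rng(4)
    img = np.full((8, 8, 3), 128, dtype=np.uint8)
    mask = np.zeros((8, 8), dtype=bool)
    ai, am = seg.augment_pair(img, mask, cfg, rng)
    np.testing.assert_array_equal(am, mask)
    assert (ai != img).any()


# ---------------------------------------------------------------------------
# binarize / evaluate
# ---------------------------------------------------------------------------

def test_binarize_empty():
    assert not seg.binarize(np.zeros((8, 8))).any()


def test_binarize_threshold_inclusive():
    scores = np.array([[0.49, 0.50, 0.51]])
    np.testing.assert_array_equal(seg.binarize(scores), [[False, True, True]])


def test_binarize_monotone_in_threshold():
    rng = np.random.default_rng(0)
    scores = rng.random((64, 64))
    prev = None
    for th in (0.1, 0.3, 0.5, 0.7, 0.9):
        mask = seg.binarize(scores, th)
        if prev is not None:
            assert not (mask & ~prev).any()  # raising th never adds pixels
        prev = mask


def test_binarize_rejects_bad_threshold():
    with pytest.raises(ValueError):
        seg.binarize(np.zeros((4, 4)), threshold=0.0)
    with pytest.raises(ValueError):
        seg.binarize(np.zeros((4, 4)), threshold=1.0)


def test_evaluate_perfect():
    truth = np.zeros((16, 16), dtype=bool)
    truth[4:8, 4:8] = True
    m = seg.evaluate_segmentation(truth, truth)
    assert (m.dice, m.precision, m.recall) == (1.0, 1.0, 1.0)


def test_evaluate_disjoint():
    a = np.zeros((16, 16), dtype=bool)
    b = np.zeros((16, 16), dtype=bool)
    a[0:4] = True
    b[8:12] = True
    m = seg.evaluate_segmentation(a, b)
    assert (m.dice, m.precision, m.recall) == (0.0, 0.0, 0.0)


def test_evaluate_analytic_counts():
    truth = np.zeros((32, 32), dtype=bool)
    truth[:10, :10] = True  # 100 px
    pred = truth.copy()
    pred[20:30, 20:30] = True  # + 100 disjoint px
    m = seg.evaluate_segmentation(pred, truth)
    assert m.precision == pytest.approx(0.5)
    assert m.recall == pytest.approx(1.0)
    assert m.dice == pytest.approx(2 / 3, rel=1e-9)


def test_evaluate_both_empty_convention():
    z = np.zeros((8, 8), dtype=bool)
    m = seg.evaluate_segmentation(z, z)
    assert (m.dice, m.precision, m.recall) == (1.0, 1.0, 1.0)
    nz = z.copy()
    nz[0, 0] = True
    m2 = seg.evaluate_segmentation(nz, z)
    assert (m2.dice, m2.precision, m2.recall) == (0.0, 0.0, 0.0)


def test_evaluate_symmetry():
    rng = np.random.default_rng(5)
    a = rng.random((32, 32)) < 0.3
    b = rng.random((32, 32)) < 0.3
    m1 = seg.evaluate_segmentation(a, b)
    m2 = seg.evaluate_segmentation(b, a)
    assert m1.precision == pytest.approx(m2.recall)
    assert m1.recall == pytest.approx(m2.precision)
    assert m1.dice == pytest.approx(m2.dice)


def test_evaluate_shape_mismatch():
    with pytest.raises(ValueError):
        seg.evaluate_segmentation(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


def test_dice_consistency_identity():
    rng = np.random.default_rng(6)
    a = rng.random((32, 32)) < 0.4
    b = rng.random((32, 32)) < 0.4
    m = seg.evaluate_segmentation(a, b)
    if m.precision + m.recall > 0:
        assert m.dice == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall)
        )


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def test_scoremap_range_and_shape():
    net = UNet(in_ch=3, depth=2, base=4, seed=0)
    img = np.random.default_rng(0).integers(0, 255, (70, 90, 3), dtype=np.uint8)
    cfg = seg.SegmentationConfig(tile_size=64, tile_overlap=16)
    score = seg.predict_scoremap(net, img, cfg)
    assert score.shape == (70, 90)
    assert score.min() >= 0.0 and score.max() <= 1.0


def test_scoremap_deterministic():
    net = UNet(in_ch=3, depth=2, base=4, seed=0)
    img = np.random.default_rng(1).integers(0, 255, (64, 64, 3), dtype=np.uint8)
    s1 = seg.predict_scoremap(net, img, TINY)
    s2 = seg.predict_scoremap(net, img, TINY)
    np.testing.assert_array_equal(s1, s2)


def test_tiled_vs_single_pass():
    net = UNet(in_ch=3, depth=3, base=4, seed=2)
    sample = _tiny_sample(seed=9, size=160)
    whole = seg.SegmentationConfig(tile_size=256, tile_overlap=32)
    tiled = seg.SegmentationConfig(tile_size=96, tile_overlap=24)
    s_whole = seg.predict_scoremap(net, sample.image, whole)
    s_tiled = seg.predict_scoremap(net, sample.image, tiled)
    assert np.abs(s_whole - s_tiled).mean() <= 0.02


def test_small_image_padded_not_error():
    net = UNet(in_ch=3, depth=2, base=4, seed=0)
    img = np.random.default_rng(2).integers(0, 255, (20, 28, 3), dtype=np.uint8)
    score = seg.predict_scoremap(net, img, seg.SegmentationConfig())
    assert score.shape == (20, 28)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def test_train_determinism():
    s1, s2 = _tiny_sample(1), _tiny_sample(2)
    state_a, log_a = seg.train_segmenter([s1], [s2], TINY)
    state_b, log_b = seg.train_segmenter([s1], [s2], TINY)
    assert log_a.best_val_dice == log_b.best_val_dice
    for wa, wb in zip(state_a.weights, state_b.weights):
        np.testing.assert_array_equal(wa, wb)


def test_train_overfit_single_image():
    # easy image (low noise, thick vessels, no distractors): the network
    # must be able to memorize it nearly perfectly
    params = syn.TreeParams(n_roots=2, diameter_range=(5.0, 14.0),
                            deep_fraction=0.0, branch_probability=0.05)
    sample = syn.make_sample((96, 96), params, syn.RenderStyle(noise_sd=2.0),
                             seed=5)
    cfg = seg.SegmentationConfig(
        depth=3, base_channels=8, crop_size=96, crops_per_image=4, batch_size=4,
        max_epochs=40, patience=40, learning_rate=3e-3,
        flip_lr_prob=0.0, flip_ud_prob=0.0, rotations=(0,),
        color_shift=0.0, spatial_shift=0.0, tile_size=96, tile_overlap=16, seed=0,
    )
    _, log = seg.train_segmenter([sample], [sample], cfg)
    assert log.best_val_dice >= 0.95


def test_train_best_checkpoint_not_worse_than_first_epoch():
    s1, s2 = _tiny_sample(1), _tiny_sample(2)
    _, log = seg.train_segmenter([s1], [s2], TINY)
    assert log.best_val_dice >= log.epochs[0]["val_dice"]


def test_train_empty_dataset_rejected():
    with pytest.raises(ValueError):
        seg.train_segmenter([], [_tiny_sample(1)], TINY)
    with pytest.raises(ValueError):
        seg.train_segmenter([_tiny_sample(1)], [], TINY)


def test_model_state_roundtrip(tmp_path):
    s1, s2 = _tiny_sample(1), _tiny_sample(2)
    state, _ = seg.train_segmenter([s1], [s2], TINY)
    path = tmp_path / "model.npz"
    state.save(path)
    loaded = seg.ModelState.load(path)
    assert loaded.config_hash == state.config_hash
    for a, b in zip(state.weights, loaded.weights):
        np.testing.assert_array_equal(a, b)
    img = s2.image
    np.testing.assert_array_equal(
        seg.predict_scoremap(state, img, TINY),
        seg.predict_scoremap(loaded, img, TINY),
    )


def test_finetune_uses_init_weights():
    s1, s2 = _tiny_sample(1), _tiny_sample(2)
    state, _ = seg.train_segmenter([s1], [s2], TINY)
    cfg = seg.SegmentationConfig(**{**TINY.__dict__, "max_epochs": 1})
    state2, log2 = seg.train_segmenter([s1], [s2], cfg, init=state)
    assert state2.depth == state.depth
    assert len(log2.epochs) == 1


def test_config_validation():
    with pytest.raises(ValueError):
        seg.SegmentationConfig(threshold=0.0)
    with pytest.raises(ValueError):
        seg.SegmentationConfig(tile_size=64, tile_overlap=64)
    with pytest.raises(ValueError):
        seg.SegmentationConfig(rotations=(45,))


# ---------------------------------------------------------------------------
# per-vessel detection
# ---------------------------------------------------------------------------

def test_detection_truth_mask_detects_all(small_tree):
    mask, _ = syn.rasterize_tree(small_tree)
    res = seg.per_vessel_detection(mask, small_tree)
    assert all(row["detected"] for row in res.segments)
    diams = [s.mean_diameter() for i, s in enumerate(small_tree.segments)
             if not s.deep]
    assert res.min_detected_diameter == pytest.approx(min(diams))
    assert res.max_detected_diameter == pytest.approx(max(diams))


def test_detection_empty_mask(small_tree):
    empty = np.zeros(small_tree.canvas_size, dtype=bool)
    res = seg.per_vessel_detection(empty, small_tree)
    assert not any(row["detected"] for row in res.segments)
    assert res.min_detected_diameter is None


def test_detection_partial_coverage():
    # two disjoint constructed segments; predict exactly one of them
    a = syn.Segment(points=np.array([[20.0, 20.0], [20.0, 100.0]]),
                    radii=np.array([3.0, 3.0]))
    b = syn.Segment(points=np.array([[90.0, 20.0], [90.0, 100.0]]),
                    radii=np.array([3.0, 3.0]))
    tree = syn.VesselTree((128, 128), [a, b])
    pred = np.zeros((128, 128), dtype=bool)
    syn._paint_segment(pred, a)
    res = seg.per_vessel_detection(pred, tree)
    flags = {row["index"]: row["detected"] for row in res.segments}
    assert flags[0] and not flags[1]
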