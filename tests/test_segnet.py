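"""Unit tests for the subvolume segmentation stage: grid, augmentation,
losses (with analytic-gradient verification), network, and merging."""

import numpy as np
import pytest

from motionseg.core_io import LabelMask, Volume, default_scheme
from motionseg.geometry import DESK_SCALE, FULL_SCALE
from motionseg.segnet import (
    AugmentConfig,
    SegLossConfig,
    SegNet,
    SegNetArch,
    SegTrainConfig,
    _seg_loss_and_grad,
    augment,
    build_grid,
    build_segnet,
    focal_loss,
    gdl,
    merge_predictions,
    rotation_matrix,
    score_subvolumes,
    seg_loss,
    train_segnet,
)


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

def test_grid_desk_scale():
    g = build_grid(DESK_SCALE.crop_lengths, DESK_SCALE.sub_shape, DESK_SCALE.step)
    assert len(g) == 27
    assert g.axis_starts == ((0, 10, 20), (0, 10, 20), (0, 12, 24))


def test_grid_validation():
    with pytest.raises(ValueError, match="exceeds"):
        build_grid((10, 10, 10), (12, 4, 4), (2, 2, 2))
    with pytest.raises(ValueError, match="step"):
        build_grid((10, 10, 10), (4, 4, 4), (5, 4, 4))


def test_grid_forces_last_start():
    g = build_grid((11, 8, 8), (4, 4, 4), (4, 4, 4))
    assert g.axis_starts[0] == (0, 4, 7)  # last start snapped to extent-sub


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def test_rotation_matrix_orthonormal():
    R = rotation_matrix((1.0, -0.5, 0.25))
    np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_augment_identity_when_prob_zero():
    s = default_scheme()
    rng = np.random.default_rng(0)
    v = Volume(data=rng.normal(size=(12, 12, 12)))
    m = LabelMask(labels=rng.integers(0, 5, (12, 12, 12)).astype(np.int32), scheme=s)
    av, am = augment((v, m), AugmentConfig(rotate_prob=0.0), rng)
    np.testing.assert_array_equal(av.data, v.data)
    np.testing.assert_array_equal(am.labels, m.labels)


def test_augment_applies_same_transform_to_both():
    s = default_scheme()
    rng = np.random.default_rng(1)
    labels = np.zeros((16, 16, 16), dtype=np.int32)
    labels[4:12, 4:12, 4:12] = 3
    v = Volume(data=(labels * 10.0).astype(np.float64))
    m = LabelMask(labels=labels, scheme=s)
    cfg = AugmentConfig(rotate_prob=1.0)
    av, am = augment((v, m), cfg, rng)
    assert av.shape == v.shape and am.shape == m.shape
    assert set(am.present_labels()) <= {0, 3}
    # intensity structure follows the rotated labels closely
    inside = am.labels == 3
    assert float(np.nanmean(av.data[inside])) > 5.0
    assert am.labels.dtype == m.labels.dtype


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _rand_probs(rng, C, shape):
    z = rng.normal(size=(C,) + shape)
    e = np.exp(z - z.max(axis=0))
    return e / e.sum(axis=0)


def test_focal_reduces_to_cross_entropy():
    rng = np.random.default_rng(2)
    probs = _rand_probs(rng, 4, (3, 3, 3))
    y = rng.integers(0, 4, (3, 3, 3))
    cfg = SegLossConfig(alpha=1.0, gamma=0.0)
    p_t = np.take_along_axis(probs, y[None], axis=0)[0]
    ce = float(np.mean(-np.log(p_t)))
    assert focal_loss(probs, y, cfg) == pytest.approx(ce)


def test_gdl_worked_example():
    """Hand evaluation on a 2-voxel, 2-class example.

    y = [0, 1]; p(class0) = [0.8, 0.4].  Counts n_0 = n_1 = 1, eps = 1 so
    both weights are 1/4 and cancel.  intersection = 0.8 + 0.6 = 1.4;
    denominator = (p + t) summed = 4.  GDL = 1 - 2*1.4/4 = 0.3.
    """
    probs = np.array([[0.8, 0.4], [0.2, 0.6]])[:, :, None, None]
    y = np.array([0, 1])[:, None, None]
    assert gdl(probs, y, eps=1.0) == pytest.approx(0.3)


def test_seg_loss_zero_iff_perfect():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 3, (4, 4, 4))
    perfect = np.moveaxis(np.eye(3)[y], -1, 0)
    assert seg_loss(perfect, y) == pytest.approx(0.0, abs=1e-9)
    imperfect = perfect * 0.9 + 0.1 / 3
    assert seg_loss(imperfect, y) > 1e-3


def test_seg_loss_weights():
    rng = np.random.default_rng(4)
    probs = _rand_probs(rng, 3, (4, 4, 4))
    y = rng.integers(0, 3, (4, 4, 4))
    cfg = SegLossConfig()
    only_f = SegLossConfig(focal_weight=1.0, gdl_weight=0.0)
    only_g = SegLossConfig(focal_weight=0.0, gdl_weight=1.0)
    assert seg_loss(probs, y, cfg) == pytest.approx(
        seg_loss(probs, y, only_f) + seg_loss(probs, y, only_g)
    )
    with pytest.raises(ValueError):
        SegLossConfig(focal_weight=0.0, gdl_weight=0.0)


def test_seg_loss_gradient_matches_finite_differences():
    rng = np.random.default_rng(5)
    logits = rng.normal(size=(2, 4, 3, 3, 3))
    y = rng.integers(0, 4, (2, 3, 3, 3))
    cfg = SegLossConfig()
    loss, grad = _seg_loss_and_grad(logits, y, cfg)
    eps = 1e-6
    for _ in range(20):
        idx = tuple(rng.integers(0, s) for s in logits.shape)
        lp = logits.copy(); lp[idx] += eps
        lm = logits.copy(); lm[idx] -= eps
        num = (_seg_loss_and_grad(lp, y, cfg)[0] - _seg_loss_and_grad(lm, y, cfg)[0]) / (2 * eps)
        assert grad[idx] == pytest.approx(num, abs=1e-6)


def test_batched_loss_matches_public_losses():
    rng = np.random.default_rng(6)
    logits = rng.normal(size=(1, 3, 4, 4, 4))
    y = rng.integers(0, 3, (1, 4, 4, 4))
    cfg = SegLossConfig()
    loss, _ = _seg_loss_and_grad(logits, y, cfg)
    z = logits[0] - logits[0].max(axis=0)
    probs = np.exp(z) / np.exp(z).sum(axis=0)
    assert loss == pytest.approx(seg_loss(probs, y[0], cfg))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

def test_segnet_census_and_shapes():
    model = build_segnet(n_classes=5, base_channels=4, seed=0)
    census = model.layer_census()
    assert census["pool"] == 0
    assert census["skip_connections"] == 2
    assert census["batchnorm"] == census["conv"] - 1  # all but the 1x1 output
    x = np.random.default_rng(0).normal(size=(2, 1, 20, 20, 24))
    out = model.forward(x, training=False)
    assert out.shape == (2, 5, 20, 20, 24)


def test_segnet_rejects_pooling():
    with pytest.raises(ValueError, match="pooling"):
        SegNet(SegNetArch(n_classes=3, use_pooling=True))


def test_segnet_save_load_roundtrip(tmp_path):
    model = build_segnet(n_classes=4, base_channels=4, seed=1)
    x = np.random.default_rng(1).normal(size=(1, 1, 12, 12, 12))
    ref = model.forward(x, training=False)
    model.save(tmp_path / "seg_model")
    loaded = SegNet.load(tmp_path / "seg_model")
    np.testing.assert_allclose(loaded.forward(x, training=False), ref, atol=1e-6)


def test_segnet_end_to_end_gradients():
    """Finite-difference check of the full backprop (including both skip
    connections) on a small float64 instance."""
    import motionseg.nn as nn

    model = build_segnet(n_classes=3, base_channels=2, seed=2)
    # promote to float64 for FD precision
    for layer in model._all_layers:
        layer.dtype = np.float64
        layer.params = [p.astype(np.float64) for p in layer.params]
        layer.grads = [g.astype(np.float64) for g in layer.grads]
        if isinstance(layer, nn.BatchNorm):
            layer.running_mean = layer.running_mean.astype(np.float64)
            layer.running_var = layer.running_var.astype(np.float64)
    rng = np.random.default_rng(3)
    x = rng.normal(size=(1, 1, 8, 8, 8))
    y = rng.integers(0, 3, (1, 8, 8, 8))
    cfg = SegLossConfig()

    def loss():
        logits = model.forward(x, training=False)
        return _seg_loss_and_grad(logits, y, cfg)[0]

    model.zero_grad()
    logits = model.forward(x, training=False)
    _, dlogits = _seg_loss_and_grad(logits, y, cfg)
    model.backprop(dlogits)

    params = model.parameters()
    grads = model.gradients()
    eps = 1e-5
    for p, g in zip(params[:4] + params[-2:], grads[:4] + grads[-2:]):
        for _ in range(3):
            idx = tuple(rng.integers(0, s) for s in p.shape) if p.ndim else ()
            orig = p[idx]
            p[idx] = orig + eps; fp = loss()
            p[idx] = orig - eps; fm = loss()
            p[idx] = orig
            assert g[idx] == pytest.approx((fp - fm) / (2 * eps), abs=1e-6)


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def test_merge_predictions_coverage_and_errors():
    grid = build_grid((8, 8, 8), (4, 4, 4), (2, 2, 2))
    C = 3
    subs = [(st, np.ones((C, 4, 4, 4))) for st in grid.starts]
    merged = merge_predictions(subs, grid)
    assert merged.coverage.min() >= 1
    assert merged.coverage.max() == 8  # corners of 8 overlapping subvolumes
    np.testing.assert_allclose(merged.scores, 1.0)  # sum/coverage normalizes
    with pytest.raises(ValueError, match="missing"):
        merge_predictions(subs[:-1], grid)
    bad = [(st, np.ones((C, 3, 4, 4))) for st in grid.starts]
    with pytest.raises(ValueError, match="shape"):
        merge_predictions(bad, grid)


def test_argmax_tie_breaks_to_lowest_id():
    grid = build_grid((4, 4, 4), (4, 4, 4), (4, 4, 4))
    scores = np.ones((3, 4, 4, 4))
    merged = merge_predictions([((0, 0, 0), scores)], grid)
    assert merged.argmax_labels().max() == 0


# ---------------------------------------------------------------------------
# Training (tiny smoke)
# ---------------------------------------------------------------------------

def test_train_segnet_improves_over_initialization():
    from motionseg.geometry import Geometry

    tiny = Geometry(conform_shape=(16, 16, 16), crop_lengths=(8, 8, 8))
    s = default_scheme()
    rng = np.random.default_rng(0)
    pairs = []
    for i in range(3):
        labels = np.zeros((8, 8, 8), dtype=np.int32)
        labels[2:6, 2:6, 2:6] = 1
        vol = labels * 2.0 + rng.normal(0, 0.1, (8, 8, 8))
        pairs.append((Volume(data=vol), LabelMask(labels=labels, scheme=s)))
    log = []
    cfg = SegTrainConfig(max_epochs=8, seed=0, base_channels=2)
    model = train_segnet(pairs[:2], pairs[2:], cfg, geometry=tiny, n_classes=2,
                         log=log)
    assert len(log) >= 1
    # the restored best model is at least as good as the first epoch
    assert min(e["val_loss"] for e in log) <= log[0]["val_loss"]
    with pytest.raises(ValueError, match=">= 2 training"):
        train_segnet(pairs[:1], pairs[2:], cfg, geometry=tiny, n_classes=2)
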