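"""Fusion layer, task heads and the weighted multi-task objective."""

import numpy as np
import pytest

from treefuse.backbone import tiny_backbone_config
from treefuse.model import (
    FusionModel,
    LossWeights,
    ModelConfig,
    fit_head_hidden,
    load_checkpoint,
    save_checkpoint,
    total_loss,
)
from treefuse.nn import tensor as T
from treefuse.nn.tensor import Tensor

rng = np.random.default_rng(21)


@pytest.fixture(scope="module")
def tiny_model():
    return FusionModel(ModelConfig(backbone=tiny_backbone_config(96),
                                   sensor_dim=30, head_hidden=64, seed=4))


def test_reference_fusion_width():
    from treefuse.backbone import efficientnet_b0_config
    cfg = ModelConfig(backbone=efficientnet_b0_config(), sensor_dim=30)
    assert cfg.fusion_width == 32 + 1280 == 1312


def test_fuse_concatenation_sensor_block_first(tiny_model):
    a = Tensor(rng.normal(size=(2, 32)))
    b = Tensor(rng.normal(size=(2, 320)))
    f = tiny_model.fuse(a, b)
    assert f.shape == (2, 352)
    np.testing.assert_array_equal(f.data[:, :32], a.data)
    # zero image embedding leaves the sensor block unchanged
    f0 = tiny_model.fuse(a, Tensor(np.zeros((2, 320))))
    np.testing.assert_array_equal(f0.data[:, :32], a.data)


def test_fuse_missing_modality_is_error(tiny_model):
    with pytest.raises(ValueError, match="missing"):
        tiny_model.fuse(None, Tensor(np.zeros((1, 320))))


def test_sensor_mlp_shapes_and_zero_limit():
    model = FusionModel(ModelConfig(backbone=None, sensor_dim=30,
                                    head_hidden=16, seed=0))
    emb = model.sensor_mlp(rng.normal(size=(5, 30)).astype(np.float32))
    assert emb.shape == (5, 32)
    for p in model.mlp.parameters():
        p.data[...] = 0.0
    emb0 = model.sensor_mlp(rng.normal(size=(3, 30)).astype(np.float32))
    np.testing.assert_array_equal(emb0.data, np.zeros((3, 32)))
    with pytest.raises(ValueError, match="width"):
        model.sensor_mlp(np.zeros((2, 31), dtype=np.float32))


def test_softmax_simplex_and_shift_invariance(tiny_model):
    f = Tensor(rng.normal(size=(8, 352)).astype(np.float32))
    logits = tiny_model.head_classify(f)
    probs = T.softmax(logits)
    assert np.all(probs >= 0)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    shifted = T.softmax(Tensor(logits.data + 7.3))
    np.testing.assert_allclose(shifted, probs, atol=1e-6)
    equal = T.softmax(Tensor(np.zeros((1, 4))))
    np.testing.assert_allclose(equal, 0.25)


def test_heads_share_no_parameters(tiny_model):
    f = Tensor(rng.normal(size=(4, 352)).astype(np.float32))
    co2_before = tiny_model.head_regress_co2(f).data.copy()
    cls_before = tiny_model.head_classify(f).data.copy()
    saved = tiny_model.heads["o2"].fc1.weight.data.copy()
    tiny_model.heads["o2"].fc1.weight.data += 1.0
    try:
        assert np.array_equal(tiny_model.head_regress_co2(f).data, co2_before)
        assert np.array_equal(tiny_model.head_classify(f).data, cls_before)
    finally:
        tiny_model.heads["o2"].fc1.weight.data = saved


def test_zero_regression_head_predicts_target_mean():
    from treefuse.sensors import StandardizationStats, invert_target_standardization
    model = FusionModel(ModelConfig(backbone=None, sensor_dim=6,
                                    head_hidden=8, seed=0))
    for p in model.heads["o2"].parameters():
        p.data[...] = 0.0
    out = model.predict(sensors=rng.normal(size=(3, 6)).astype(np.float32))
    np.testing.assert_array_equal(out.o2, np.zeros(3))
    stats = StandardizationStats({}, {}, {"O2_rate": 4.2}, {"O2_rate": 1.7})
    np.testing.assert_allclose(
        invert_target_standardization(out.o2, "O2_rate", stats), 4.2)


def test_loss_weight_normalisation():
    w = LossWeights()
    assert w.total == 1.0
    with pytest.raises(ValueError):
        LossWeights(cls=-0.1)


def _fake_outputs(ce_target: float, o2_err: float, co2_err: float):
    """Outputs whose loss components equal the requested values exactly."""
    # CE for label 0 with logits [0, z, -inf, -inf]: log(1 + e^z) = ce_target
    z = np.log(np.expm1(ce_target)) if ce_target > 0 else -1e9
    logits = np.array([[0.0, z, -1e9, -1e9]])
    return ({"logits": Tensor(logits), "o2": Tensor(np.array([o2_err])),
             "co2": Tensor(np.array([co2_err]))},
            np.array([0]), np.zeros(1), np.zeros(1))


@pytest.mark.parametrize("components,expected", [
    ((1.0, 1.0, 1.0), 1.0),   # weights sum to one
    ((2.0, 0.0, 0.0), 0.8),   # 0.4 * 2
    ((0.0, 0.0, 0.0), 0.0),   # perfect predictions
])
def test_total_loss_arithmetic(components, expected):
    outputs, labels, t_o2, t_co2 = _fake_outputs(*components)
    losses = total_loss(outputs, labels, t_o2, t_co2)
    for got, want in zip((losses["cls"], losses["o2"], losses["co2"]), components):
        assert float(got.data) == pytest.approx(want, abs=1e-9)
    assert float(losses["total"].data) == pytest.approx(expected, abs=1e-9)


def test_total_loss_convex_combination_bound():
    for _ in range(20):
        comps = rng.uniform(0, 5, size=3)
        outputs, labels, t_o2, t_co2 = _fake_outputs(*comps)
        lt = float(total_loss(outputs, labels, t_o2, t_co2)["total"].data)
        assert comps.min() - 1e-9 <= lt <= comps.max() + 1e-9


def test_total_loss_rejects_bad_labels(tiny_model):
    outputs, _, t_o2, t_co2 = _fake_outputs(1.0, 0.0, 0.0)
    with pytest.raises(ValueError):
        total_loss(outputs, np.array([5]), t_o2, t_co2)


def test_gradient_flows_to_every_parameter_tensor(tiny_model):
    """Shared-trunk + decoupled-heads wiring: the weighted total loss sends
    a nonzero gradient into every trainable tensor."""
    model = tiny_model
    model.train()
    images = rng.normal(size=(8, 3, 96, 96)).astype(np.float32)
    sensors = rng.normal(size=(8, 30)).astype(np.float32)
    out = model(images=images, sensors=sensors)
    losses = total_loss(out, labels=np.array([0, 1, 2, 3, 0, 1, 2, 3]),
                        o2_targets=rng.normal(size=8).astype(np.float32),
                        co2_targets=rng.normal(size=8).astype(np.float32))
    model.zero_grad()
    losses["total"].backward()
    dead = [name for name, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert dead == []


def test_head_decoupling_in_loss(tiny_model):
    """Zeroing one head's parameters changes only that head's component."""
    model = tiny_model
    images = rng.normal(size=(4, 3, 96, 96)).astype(np.float32)
    sensors = rng.normal(size=(4, 30)).astype(np.float32)
    labels = np.array([0, 1, 2, 3])
    t = rng.normal(size=4).astype(np.float32)

    def components():
        out = model.predict(images=images, sensors=sensors)
        model.eval()
        fwd = model(images=images, sensors=sensors)
        model.train()
        losses = total_loss(fwd, labels, t, t)
        return {k: float(v.data) for k, v in losses.items()}

    before = components()
    saved = {i: p.data.copy() for i, p in enumerate(model.heads["o2"].parameters())}
    for p in model.heads["o2"].parameters():
        p.data[...] = 0.0
    after = components()
    for i, p in enumerate(model.heads["o2"].parameters()):
        p.data = saved[i]
    assert after["cls"] == before["cls"]
    assert after["co2"] == before["co2"]
    assert after["o2"] != before["o2"]


def test_head_sizing_meets_parameter_budget():
    assert fit_head_hidden(4_007_548, sensor_dim=30) == 344


def test_checkpoint_round_trip(tmp_path):
    model = FusionModel(ModelConfig(backbone=None, sensor_dim=6,
                                    head_hidden=8, seed=2))
    sensors = rng.normal(size=(3, 6)).astype(np.float32)
    before = model.predict(sensors=sensors)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, model, extra={"note": "fit"})
    loaded, extra = load_checkpoint(path)
    assert extra == {"note": "fit"}
    after = loaded.predict(sensors=sensors)
    np.testing.assert_array_equal(before.probs, after.probs)
    np.testing.assert_array_equal(before.o2, after.o2)
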