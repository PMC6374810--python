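"""Training recipe: schedules, loss, sampling, optimizer, smoke training."""

import numpy as np
import pytest

from msdseg import nn
from msdseg.msdensenet import MSDenseNet, NetworkConfig
from msdseg.training import (SGD, LossCurve, TrainConfig, cross_entropy_loss,
                             init_weights, poly_lr, sample_subvolume, step_lr,
                             train)
from msdseg.volio import LabelMask, VolumeImage


def test_poly_lr_endpoints_and_monotonicity():
    cfg = TrainConfig()
    assert poly_lr(0, cfg) == pytest.approx(0.05)
    assert poly_lr(cfg.max_iterations, cfg) == 0.0
    vals = [poly_lr(i, cfg) for i in range(0, cfg.max_iterations, 4000)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    # half-way value of the closed form
    assert poly_lr(20000, cfg) == pytest.approx(0.05 * 0.5 ** 0.9)
    with pytest.raises(ValueError):
        poly_lr(-1, cfg)


def test_step_lr_divides_by_ten():
    cfg = TrainConfig(lr_schedule="step", step_epochs=2, patches_per_volume=4,
                      batch_size=4)
    # 1 volume -> 1 iteration per epoch -> drop every 2 iterations
    assert step_lr(0, cfg, 1) == pytest.approx(0.05)
    assert step_lr(1, cfg, 1) == pytest.approx(0.05)
    assert step_lr(2, cfg, 1) == pytest.approx(0.005)
    assert step_lr(4, cfg, 1) == pytest.approx(0.0005)


def test_cross_entropy_uniform_is_ln2(rng):
    p = np.full((2, 2, 4, 4, 4), 0.5)
    labels = rng.integers(0, 2, (2, 4, 4, 4))
    assert cross_entropy_loss(p, labels) == pytest.approx(np.log(2))
    # perfect prediction -> ~0
    lab = np.zeros((1, 2, 2, 2), np.int64)
    perfect = np.zeros((1, 2, 2, 2, 2))
    perfect[:, 0] = 1.0
    assert cross_entropy_loss(perfect, lab) == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError, match="shape"):
        cross_entropy_loss(np.zeros((1, 2, 4, 4, 4)), np.zeros((1, 4, 4), np.int64))


def _pair(rng, shape=(20, 20, 20)):
    sp = (1.0, 1.0, 1.0)
    vol = rng.standard_normal(shape).astype(np.float32)
    mask = np.zeros(shape, np.uint8)
    mask[4:8, 5:9, 6:10] = 1
    return VolumeImage(vol, sp), LabelMask(mask, sp)


def test_sample_subvolume_alignment(rng):
    """Sampling the mask itself as the volume must give patch == label."""
    _, mask = _pair(rng)
    vol = VolumeImage(mask.data.astype(np.float32), mask.spacing)
    for _ in range(20):
        patch, label = sample_subvolume(vol, mask, rng, size=8, p_fg=0.5)
        assert patch.shape == label.shape == (8, 8, 8)
        np.testing.assert_array_equal(patch.astype(np.uint8), label)


def test_sample_subvolume_foreground_bias(rng):
    vol, mask = _pair(rng)
    hits = sum(sample_subvolume(vol, mask, rng, 8, p_fg=1.0)[1].any()
               for _ in range(25))
    assert hits == 25  # fg-centered patches always contain foreground
    with pytest.raises(ValueError, match="smaller"):
        sample_subvolume(vol, mask, rng, size=32, p_fg=0.5)


def test_augmentation_preserves_alignment(rng):
    from msdseg.training import _augment
    _, mask = _pair(rng)
    vol = VolumeImage(mask.data.astype(np.float32), mask.spacing)
    patch, label = sample_subvolume(vol, mask, rng, 8, p_fg=1.0)
    ap, al = _augment(patch, label, rng)
    np.testing.assert_array_equal(ap.astype(np.uint8), al)
    assert al.sum() == label.sum()


def test_sgd_hand_computed_step():
    p = nn.Tensor(np.array([1.0, -2.0]), requires_grad=True)
    opt = SGD([("p", p)], momentum=0.5, weight_decay=0.1)
    p.grad = np.array([0.5, 0.5])
    opt.step(lr=0.1)
    # v = g + wd*p = [0.6, 0.3]; p -= 0.1*v
    np.testing.assert_allclose(p.data, [1.0 - 0.06, -2.0 - 0.03])
    assert p.grad is None
    p.grad = np.array([0.0, 0.0])
    opt.step(lr=0.1)
    # v = 0.5*[0.6, 0.3] + wd*p
    v = 0.5 * np.array([0.6, 0.3]) + 0.1 * np.array([0.94, -2.03])
    np.testing.assert_allclose(p.data, np.array([0.94, -2.03]) - 0.1 * v)


def test_init_weights_statistics(tiny_network_config):
    net = MSDenseNet(tiny_network_config)
    init_weights(net, TrainConfig(init_sigma=0.01), seed=0)
    ws = np.concatenate([p.data.ravel() for n, p in net.parameters()
                         if n.endswith(".weight")])
    assert abs(ws.mean()) < 0.002
    assert 0.008 < ws.std() < 0.012
    gammas = [p.data for n, p in net.parameters() if n.endswith(".gamma")]
    assert all(np.all(g == 1.0) for g in gammas)
    # reproducible
    net2 = init_weights(MSDenseNet(tiny_network_config), TrainConfig(), seed=0)
    for (_, a), (_, b) in zip(net.parameters(), net2.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_train_smoke_and_determinism(rng, tiny_network_config):
    vol, mask = _pair(rng, (16, 16, 16))
    cfg = TrainConfig(max_iterations=3, batch_size=1, subvolume_size=8, seed=4)
    net, curve = train(MSDenseNet(tiny_network_config), [(vol, mask)], cfg)
    assert len(curve.train_loss) == 3
    assert all(np.isfinite(curve.train_loss))
    net2, curve2 = train(MSDenseNet(tiny_network_config), [(vol, mask)], cfg)
    np.testing.assert_allclose(curve.train_loss, curve2.train_loss, rtol=1e-6)
    df = curve.to_frame()
    assert list(df.columns) == ["iteration", "train_loss", "val_loss"]
    with pytest.raises(ValueError, match="empty"):
        train(MSDenseNet(tiny_network_config), [], cfg)


def test_validation_loss_decreases_on_held_out_phantoms(small_phantom_config,
                                                        tiny_network_config):
    """Median over 3 seeds: validation loss on held-out phantoms is lower at
    the end of a desk-scale run than at its start (no serious overfitting at
    this scale)."""
    from msdseg.phantom import generate_phantom
    from msdseg.training import validation_loss
    from msdseg.volio import normalize_volume
    deltas = []
    for seed in range(3):
        tr = generate_phantom(small_phantom_config, seed=50 + seed)
        va = generate_phantom(small_phantom_config, seed=60 + seed)
        pairs = [(normalize_volume(tr[0]), tr[1])]
        vpairs = [(normalize_volume(va[0]), va[1])]
        cfg = TrainConfig(max_iterations=30, batch_size=2, subvolume_size=16,
                          seed=seed)
        net = MSDenseNet(tiny_network_config)
        init_weights(net, cfg, cfg.seed)
        start = validation_loss(net, vpairs, stride=16)
        net, _ = train(net, pairs, cfg, initialize=False)
        end = validation_loss(net, vpairs, stride=16)
        deltas.append(end - start)
    assert np.median(deltas) < 0


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(base_lr=0.0).validate()
    with pytest.raises(ValueError):
        TrainConfig(momentum=1.0).validate()
    with pytest.raises(ValueError):
        TrainConfig(lr_schedule="cosine").validate()


def test_loss_curve_csv_roundtrip(tmp_path):
    c = LossCurve(train_loss=[0.7, 0.5, 0.3], val_iterations=[2], val_loss=[0.6])
    c.to_csv(tmp_path / "loss.csv")
    import pandas as pd
    df = pd.read_csv(tmp_path / "loss.csv")
    assert df["train_loss"].tolist() == [0.7, 0.5, 0.3]
    assert df["val_loss"].iloc[1] == 0.6 and np.isnan(df["val_loss"].iloc[0])
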