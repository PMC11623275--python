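"""Architecture invariants of the multi-task V-shaped network."""

import numpy as np
import pytest

from glaucnet.network import (
    MTLNet,
    N_DOWNSAMPLES,
    NetworkSpec,
    SEG_CLASSES,
    build_network,
)


def rand_images(n, size, channels=3, seed=0):
    return np.random.default_rng(seed).random((n, size, size, channels),
                                              dtype=np.float32)


@pytest.fixture(scope="module")
def small_net():
    return build_network(NetworkSpec(input_size=32, base_channels=4, fc_hidden=16),
                         seed=0)


@pytest.mark.parametrize("size", [64, 128, 224])
def test_stage_bookkeeping(size):
    """Spatial sides halve and channels double at every encoder stage."""
    spec = NetworkSpec(input_size=size, base_channels=8)
    assert spec.stage_sides == [size // 2**s for s in range(5)]
    assert spec.stage_channels == [8 * 2**s for s in range(5)]
    net = build_network(spec, seed=0)
    feats = net.encode(rand_images(1, size))
    for s, f in enumerate(feats):
        assert f.shape == (1, size // 2**s, size // 2**s, 8 * 2**s)
        assert np.all(np.isfinite(f))
    # decoder restores the input resolution
    seg = net.decode(feats)
    assert seg.shape[1:3] == (size, size)
    np.testing.assert_allclose(seg.sum(axis=-1), 1.0, atol=1e-5)
    # classifier emits a normalized 2-vector
    cls = net.classify(feats)
    assert cls.shape == (1, 2)
    assert cls.min() >= 0
    np.testing.assert_allclose(cls.sum(axis=1), 1.0, atol=1e-6)


@pytest.mark.parametrize("size", [100, 50, 17])
def test_indivisible_input_size_rejected(size):
    with pytest.raises(ValueError):
        NetworkSpec(input_size=size)


def test_spec_validation():
    with pytest.raises(ValueError):
        NetworkSpec(input_size=64, fusion_stages=())
    with pytest.raises(ValueError):
        NetworkSpec(input_size=64, fusion_stages=(6,))
    with pytest.raises(ValueError):
        NetworkSpec(input_size=64, spatial_dims=4)
    with pytest.raises(ValueError):
        NetworkSpec(input_size=64, dropout_rate=1.0)
    spec = NetworkSpec(input_size=64)
    assert NetworkSpec.from_dict(spec.to_dict()) == spec


def test_encoder_deterministic_and_shape_checked(small_net):
    x = rand_images(2, 32, seed=1)
    f1 = small_net.encode(x)
    f2 = small_net.encode(x)
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError):
        small_net.encode(rand_images(2, 64))


def test_skip_connections_are_live(small_net):
    """Zeroing the skip tensors changes the decoder output."""
    feats = small_net.encode(rand_images(1, 32, seed=2))
    seg = small_net.decode(feats)
    ablated = [np.zeros_like(f) for f in feats[:-1]] + [feats[-1]]
    seg_ablated = small_net.decode(ablated)
    assert not np.allclose(seg, seg_ablated)


def test_fused_vector_length_matches_fusion_stages():
    spec = NetworkSpec(input_size=32, base_channels=4, fusion_stages=(2, 5))
    assert spec.fused_length == 4 * 2 + 4 * 16
    net = build_network(spec, seed=0)
    cls = net.classify(net.encode(rand_images(1, 32)))
    assert cls.shape == (1, 2)


def test_forward_batched_and_order_preserving(small_net):
    x = rand_images(5, 32, seed=3)
    out = small_net.forward(x)
    assert out.seg_map.shape == (5, 32, 32, SEG_CLASSES)
    assert out.cls_probs.shape == (5, 2)
    single = small_net.forward(x[2:3])
    np.testing.assert_allclose(single.cls_probs[0], out.cls_probs[2], atol=1e-5)


def test_evaluation_mode_is_deterministic(small_net):
    x = rand_images(2, 32, seed=4)
    a = small_net.forward(x)
    b = small_net.forward(x)
    np.testing.assert_array_equal(a.cls_probs, b.cls_probs)
    np.testing.assert_array_equal(a.seg_map, b.seg_map)


def test_encoder_shared_once_per_forward(small_net, monkeypatch):
    calls = {"n": 0}
    orig = MTLNet.encode

    def counting(self, x, training=False):
        calls["n"] += 1
        return orig(self, x, training)

    monkeypatch.setattr(MTLNet, "encode", counting)
    small_net.forward(rand_images(1, 32))
    assert calls["n"] == 1


def test_dropout_zero_fraction():
    """Each hidden unit is zeroed with probability ~0.5 during training."""
    from glaucnet._nn import Dropout

    drop = Dropout(0.5)
    rng = np.random.default_rng(0)
    x = np.ones((100, 100), dtype=np.float32)
    zeros = 0
    for _ in range(1):
        y = drop.forward(x, training=True, rng=rng)
        zeros += float(np.mean(y == 0))
    assert abs(zeros - 0.5) < 0.02  # 10,000 draws
    # kept units are scaled by 1/(1-p); evaluation is the identity
    y = drop.forward(x, training=True, rng=rng)
    assert set(np.unique(y)) <= {0.0, 2.0}
    np.testing.assert_array_equal(drop.forward(x, training=False), x)


def test_gradient_reaches_every_parameter():
    """One combined-loss training step produces a nonzero gradient on every
    trainable tensor (no dead branches)."""
    from glaucnet.losses import LossConfig
    from glaucnet.training import TrainConfig, train
    from glaucnet.phantom import PhantomConfig, generate_dataset
    from glaucnet.training import split_dataset

    ds = generate_dataset(PhantomConfig(n_images=24, image_size=32, seed=5,
                                        glaucoma_fraction=0.5,
                                        label_flip_rate=0.0))
    net = build_network(NetworkSpec(input_size=32, base_channels=4, fc_hidden=16),
                        seed=0)
    cfg = TrainConfig(epochs=1, batch_size=8, learning_rate=0.0,
                      loss=LossConfig(switch_epoch=0, total_epochs=1), seed=0)
    splits = split_dataset(ds, cfg)
    # run one epoch at lr=0 so gradients are produced but weights frozen
    before = [p.value.copy() for p in net.params()]
    train(net, splits, cfg)
    for p, b in zip(net.params(), before):
        np.testing.assert_array_equal(p.value, b)  # lr=0: no-op optimizer
        assert np.abs(p.grad).max() > 0, f"dead branch: {p.name}"


def test_checkpoint_roundtrip(tmp_path, small_net):
    x = rand_images(2, 32, seed=6)
    ref = small_net.forward(x)
    path = tmp_path / "ckpt.npz"
    small_net.save(path)
    loaded = MTLNet.load(path)
    assert loaded.spec == small_net.spec
    out = loaded.forward(x)
    np.testing.assert_array_equal(out.cls_probs, ref.cls_probs)
    np.testing.assert_array_equal(out.seg_map, ref.seg_map)


def test_three_dimensional_network_smoke():
    """The blocks are dimension-parameterized; a 3-D volume passes through
    with the same halving/doubling schedule."""
    spec = NetworkSpec(input_size=16, spatial_dims=3, in_channels=1,
                       base_channels=2, fc_hidden=8)
    net = build_network(spec, seed=0)
    x = np.random.default_rng(0).random((1, 16, 16, 16, 1), dtype=np.float32)
    out = net.forward(x)
    assert out.seg_map.shape == (1, 16, 16, 16, SEG_CLASSES)
    np.testing.assert_allclose(out.cls_probs.sum(axis=1), 1.0, atol=1e-6)
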