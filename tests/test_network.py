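"""Architecture contracts, attention-gate algebra and training behavior."""

import numpy as np
import pytest

from scseseg import nn
from scseseg.errors import ConfigValueError, InvalidInputShapeError
from scseseg.network import (
    NetworkConfig,
    SCSEBlock,
    TrainConfig,
    build_network,
    count_parameters,
    cse_plus_gate,
    forward,
    scse_apply,
    sse_gate,
    train_supervised,
)
from scseseg.types import LabeledPair, LabelMap, Volume


def analytic_parameter_count(in_channels, num_classes, base, reduction):
    """Layer-by-layer hand count of the scSE-UNet parameter total."""
    ch = [base * 2 ** l for l in range(5)]

    def conv3(cin, cout):
        return cout * cin * 27 + cout

    def upconv(cin, cout):
        return cin * cout * 8 + cout

    def scse(c):
        hidden = max(1, c // reduction)
        branch = (hidden * c + hidden) + (c * hidden + c)
        return 2 * branch + (c + 1)

    total = 0
    cin = in_channels
    for l in range(4):  # encoder
        total += conv3(cin, ch[l]) + conv3(ch[l], ch[l])
        cin = ch[l]
    total += conv3(ch[3], ch[4]) + conv3(ch[4], ch[4])  # bottleneck
    for l in range(3, -1, -1):  # decoder
        total += upconv(ch[l + 1], ch[l])
        total += scse(2 * ch[l])
        total += conv3(2 * ch[l], ch[l]) + conv3(ch[l], ch[l])
    total += num_classes * ch[0] + num_classes  # final 1x1x1
    return total


@pytest.mark.parametrize(
    "in_channels,num_classes,base,reduction",
    [(1, 2, 8, 2), (1, 3, 4, 2), (2, 4, 6, 3)],
)
def test_parameter_count_matches_analytic_oracle(in_channels, num_classes, base, reduction):
    cfg = NetworkConfig(
        in_channels=in_channels, num_classes=num_classes,
        base_channels=base, se_reduction=reduction, seed=0,
    )
    net = build_network(cfg)
    assert count_parameters(net) == analytic_parameter_count(
        in_channels, num_classes, base, reduction
    )


def test_network_contains_exactly_four_scse_blocks():
    net = build_network(NetworkConfig(base_channels=2, seed=0))
    assert len(net.scse_blocks) == 4


def test_depth_is_fixed_at_four():
    with pytest.raises(ConfigValueError):
        NetworkConfig(depth=3)


def test_same_seed_gives_bit_identical_parameters():
    cfg = NetworkConfig(base_channels=4, seed=42)
    a, b = build_network(cfg), build_network(cfg)
    for pa, pb in zip(a.parameters(), b.parameters()):
        np.testing.assert_array_equal(pa.value, pb.value)


def test_forward_shape_and_softmax_normalization(rng):
    net = build_network(NetworkConfig(base_channels=2, num_classes=2, seed=0))
    vol = Volume(rng.random((32, 32, 32)), id="v")
    pm = forward(net, vol)
    assert pm.probs.shape == (2, 32, 32, 32)
    np.testing.assert_allclose(pm.probs.sum(axis=0), 1.0, atol=1e-6)


def test_non_divisible_shape_error_names_axis(rng):
    net = build_network(NetworkConfig(base_channels=2, seed=0))
    vol = Volume(rng.random((30, 32, 32)), id="v")
    with pytest.raises(InvalidInputShapeError, match="axis H"):
        forward(net, vol)


def test_inference_is_deterministic(rng):
    net = build_network(NetworkConfig(base_channels=2, seed=1))
    vol = Volume(rng.random((16, 16, 16)), id="v")
    np.testing.assert_array_equal(forward(net, vol).probs, forward(net, vol).probs)


# -- attention-block algebra ------------------------------------------


def _zeroed_block(channels=4, reduction=2, fusion="add"):
    blk = SCSEBlock(channels, reduction, fusion, np.random.default_rng(0))
    for p in blk.params():
        p.value[...] = 0.0
    return blk


def test_channel_gate_is_half_with_zeroed_parameters(rng):
    blk = _zeroed_block()
    fm = rng.random((4, 3, 3, 3))
    np.testing.assert_allclose(cse_plus_gate(fm, blk), 0.5, atol=1e-7)


def test_spatial_gate_is_half_with_zeroed_parameters(rng):
    blk = _zeroed_block()
    fm = rng.random((4, 3, 3, 3))
    gate = sse_gate(fm, blk)
    assert gate.shape == (3, 3, 3)
    np.testing.assert_allclose(gate, 0.5, atol=1e-7)


def test_gates_always_lie_strictly_inside_unit_interval(rng):
    blk = SCSEBlock(4, 2, "add", np.random.default_rng(3))
    fm = rng.standard_normal((4, 5, 5, 5)) * 2
    cg, sg = cse_plus_gate(fm, blk), sse_gate(fm, blk)
    assert np.all((cg > 0) & (cg < 1))
    assert np.all((sg > 0) & (sg < 1))


def test_spatial_gate_saturates_with_large_bias(rng):
    blk = _zeroed_block()
    blk.sse_conv.bias.value[...] = 20.0
    np.testing.assert_allclose(sse_gate(rng.random((4, 3, 3, 3)), blk), 1.0, atol=1e-6)


def test_constant_channel_pools_to_its_value_under_both_pools():
    # r=1 with identity fc weights exposes the pooled values: a channel
    # constant at v>0 yields sigmoid(v + v) from both branches combined
    blk = SCSEBlock(2, 1, "add", np.random.default_rng(0))
    for p in blk.params():
        p.value[...] = 0.0
    for fc in (blk.max_fc1, blk.max_fc2, blk.avg_fc1, blk.avg_fc2):
        fc.weight.value[...] = np.eye(2, dtype=nn.DTYPE)
    fm = np.zeros((2, 3, 3, 3))
    fm[0] = 0.3
    fm[1] = 0.7
    gate = cse_plus_gate(fm, blk)
    expected = 1.0 / (1.0 + np.exp(-2 * np.array([0.3, 0.7])))
    np.testing.assert_allclose(gate, expected, rtol=1e-6)


def test_scse_apply_zero_input_stays_zero():
    blk = SCSEBlock(4, 2, "add", np.random.default_rng(2))
    out = scse_apply(np.zeros((4, 3, 3, 3)), blk)
    np.testing.assert_array_equal(out, 0.0)


def test_add_fusion_with_forced_half_gates_is_identity(rng):
    blk = _zeroed_block(fusion="add")
    fm = rng.random((4, 4, 4, 4)).astype(np.float32)
    np.testing.assert_array_equal(scse_apply(fm, blk), fm)


def test_max_fusion_with_forced_half_gates_halves_input(rng):
    blk = _zeroed_block(fusion="max")
    fm = rng.random((4, 4, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(scse_apply(fm, blk), 0.5 * fm, rtol=1e-6)


def test_gating_scales_linearly_for_fixed_gates(rng):
    # zeroed parameters pin both gates at 0.5 independent of the input,
    # so the whole block is linear in the feature map
    blk = _zeroed_block()
    fm = rng.random((4, 4, 4, 4)).astype(np.float32)
    np.testing.assert_allclose(scse_apply(3.0 * fm, blk), 3.0 * scse_apply(fm, blk), rtol=1e-5)


def test_scse_preserves_shape(rng):
    blk = SCSEBlock(6, 2, "add", np.random.default_rng(0))
    fm = rng.random((6, 4, 4, 4))
    assert scse_apply(fm, blk).shape == fm.shape


# -- training ----------------------------------------------------------


def _tiny_pair(rng, size=16):
    vol = Volume(rng.random((size, size, size)), id="t")
    labels = LabelMap((vol.voxels > 0.5).astype(np.int64), num_classes=2)
    return LabeledPair(vol, labels)


def test_zero_epochs_is_a_noop(rng):
    net = build_network(NetworkConfig(base_channels=2, seed=0))
    before = [p.value.copy() for p in net.parameters()]
    net, history = train_supervised(net, [_tiny_pair(rng)], TrainConfig(epochs=0))
    assert history == []
    for p, b in zip(net.parameters(), before):
        np.testing.assert_array_equal(p.value, b)


def test_empty_training_set_raises(rng):
    net = build_network(NetworkConfig(base_channels=2, seed=0))
    with pytest.raises(ValueError):
        train_supervised(net, [], TrainConfig(epochs=1))


def test_training_is_reproducible_from_seed(rng):
    tcfg = TrainConfig(epochs=3, learning_rate=1e-3, seed=5)
    histories = []
    for _ in range(2):
        net = build_network(NetworkConfig(base_channels=2, seed=9))
        _, h = train_supervised(net, [_tiny_pair(np.random.default_rng(4))], tcfg)
        histories.append(h)
    assert histories[0] == histories[1]


def test_overfitting_a_single_phantom_reduces_loss(default_phantom):
    vol, lm = default_phantom
    net = build_network(NetworkConfig(base_channels=8, num_classes=3, seed=0))
    _, history = train_supervised(
        net, [LabeledPair(vol, lm)], TrainConfig(epochs=30, learning_rate=1e-3, seed=0)
    )
    assert len(history) == 30
    assert history[-1] < history[0]


def test_checkpoint_round_trip(tmp_path, rng):
    net = build_network(NetworkConfig(base_channels=2, num_classes=2, seed=3))
    vol = Volume(rng.random((16, 16, 16)), id="v")
    path = tmp_path / "ckpt.npz"
    net.save(path)
    from scseseg.network import SegmentationNetwork

    loaded = SegmentationNetwork.load(path)
    np.testing.assert_array_equal(forward(net, vol).probs, forward(loaded, vol).probs)
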