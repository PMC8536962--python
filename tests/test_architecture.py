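"""Network spec construction, structural invariants, instantiation
contracts, and the weight-initialisation statistics."""

import numpy as np
import pytest

from simounet import nn
from simounet.architecture import (
    HEAD_ORDER,
    ConfigurationError,
    NetworkSpec,
    build_simo_unet_spec,
    build_simou_spec,
    init_weights,
    instantiate,
    predict,
)
from simounet.nn import gaussian_init_sd, init_conv_kernel
from simounet.training import total_objective


def test_default_spec_structural_counts():
    spec = build_simou_spec()
    assert spec.n_side_outputs == 15
    assert spec.n_heads == 5
    assert spec.n_levels == 8
    assert spec.channels == (32, 32, 64, 64, 128, 128, 256, 512)
    assert spec.post_concat_channels == 64


def test_head_subsets_follow_concatenation_rule():
    spec = build_simou_spec()
    hd = spec.head_definitions
    assert hd["d_u"] == tuple(range(1, 16))
    assert hd["d_ux"] == tuple(range(1, 15))
    assert hd["d"] == tuple(range(1, 9))
    assert hd["u"] == tuple(range(9, 16))
    assert hd["f"] == ()


def test_width_multiplier_scales_channels():
    spec = build_simou_spec(width_multiplier=1 / 8)
    assert spec.channels == (4, 4, 8, 8, 16, 16, 32, 64)


def test_dropout_on_last_three_down_first_three_up():
    spec = build_simou_spec()
    assert spec.dropout_down_levels == (6, 7, 8)
    assert spec.dropout_up_levels == (1, 2, 3)


def test_simo_unet_spec_pattern():
    spec = build_simo_unet_spec()
    assert spec.n_side_outputs == 9
    assert spec.n_heads == 5
    assert spec.head_definitions["d"] == (1, 2, 3, 4, 5)
    assert spec.channels == (64, 128, 256, 512, 1024)


def test_indivisible_input_shape_rejected():
    with pytest.raises(ConfigurationError, match="divisible"):
        build_simou_spec((64, 64, 1), n_levels=8)


def test_spec_yaml_round_trip():
    spec = build_simou_spec((128, 128, 1), width_multiplier=0.25)
    again = NetworkSpec.from_yaml(spec.to_yaml())
    assert again == spec
    assert again.content_hash() == spec.content_hash()


def _tiny_spec(n_levels=3, size=16):
    return build_simou_spec((size, size, 1), width_multiplier=1 / 16,
                            n_levels=n_levels, dropout_rate=0.0)


def test_prediction_set_shape_contract():
    model = instantiate(_tiny_spec(), seed=0)
    x = np.random.default_rng(0).random((2, 16, 16))
    preds = predict(model, x)
    for head in HEAD_ORDER:
        assert preds[head].shape == (2, 16, 16)
        assert preds[head].min() >= 0.0 and preds[head].max() <= 1.0


def test_zero_weights_give_half_probability_everywhere():
    model = instantiate(_tiny_spec(), seed=0)
    model.zero_weights()
    preds = predict(model, np.ones((1, 16, 16), dtype=np.float32))
    for head in HEAD_ORDER:
        np.testing.assert_allclose(preds[head], 0.5, atol=1e-7)


def test_same_seed_gives_identical_initial_predictions():
    x = np.random.default_rng(5).random((2, 16, 16))
    p1 = predict(instantiate(_tiny_spec(), seed=42), x)
    p2 = predict(instantiate(_tiny_spec(), seed=42), x)
    p3 = predict(instantiate(_tiny_spec(), seed=43), x)
    np.testing.assert_array_equal(p1.p_f, p2.p_f)
    assert not np.array_equal(p1.p_f, p3.p_f)


def test_head_concat_channel_bookkeeping():
    spec = build_simou_spec((128, 128, 1), width_multiplier=1 / 16)
    model = instantiate(spec, seed=0)
    shc = spec.side_head_channels
    assert model.heads["d_u"].conv1.cin == 15 * shc
    assert model.heads["d"].conv1.cin == 8 * shc
    assert model.heads["u"].conv1.cin == 7 * shc
    assert model.heads["d_ux"].conv1.cin == 14 * shc


def test_all_heads_reach_every_level_with_gradient():
    """Deep supervision on each head must touch parameters in every
    encoder and decoder level."""
    model = instantiate(_tiny_spec(), seed=1)
    x = nn.Tensor(np.random.default_rng(2).random((1, 16, 16, 1)).astype(np.float32))
    y = (np.random.default_rng(3).random((1, 16, 16)) > 0.5).astype(np.float32)
    out = model.forward(x)
    loss = total_objective(out, y, (1.0,) * 5)
    loss.backward()
    for i, block in enumerate(model.enc):
        assert np.any(block.conv1.w.grad != 0), f"encoder level {i + 1} has zero grad"
    for i, block in enumerate(model.dec):
        assert np.any(block.conv1.w.grad != 0), f"decoder block {i + 1} has zero grad"


def test_initialization_sd_matches_sqrt_2_over_eta():
    # eta = 3*3*32 = 288 incoming nodes -> sd = sqrt(2/288)
    eta = 3 * 3 * 32
    target = gaussian_init_sd(3, 3, 32)
    assert target == pytest.approx(np.sqrt(2.0 / eta))
    cout = int(np.ceil(1e5 / eta))
    w = init_conv_kernel(np.random.default_rng(0), 3, 3, 32, cout)
    assert w.size >= 1e5
    assert abs(w.std() - target) / target < 0.05
    assert abs(w.mean()) < 0.01 * target * 10


def test_initialization_eta_two_gives_unit_sd():
    assert gaussian_init_sd(1, 1, 2) == pytest.approx(1.0)


def test_init_weights_deterministic():
    m1 = init_weights(instantiate(_tiny_spec(), seed=0), seed=9)
    m2 = init_weights(instantiate(_tiny_spec(), seed=1), seed=9)
    for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        assert n1 == n2
        np.testing.assert_array_equal(p1.data, p2.data)


def test_checkpoint_round_trip(tmp_path):
    from simounet.architecture import load_model, save_model

    model = instantiate(_tiny_spec(), seed=4)
    x = np.random.default_rng(6).random((1, 16, 16))
    before = predict(model, x)
    save_model(model, tmp_path / "model.npz", seed=4)
    reloaded = load_model(tmp_path / "model.npz")
    after = predict(reloaded, x)
    np.testing.assert_array_equal(before.stack(), after.stack())
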