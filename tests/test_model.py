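"""Architecture contracts: encoder shapes, lossless patch tiling, the
convLSTM recurrence against a literal scalar oracle, fusion composition,
and full-model forward properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akunet import nn
from akunet.model import (AKUNet, ConfigurationError, ConvLSTMParams,
                          ModelConfig, baseline_config, build_encoder,
                          build_model, convlstm_fuse, convlstm_step,
                          reassemble_patches, split_to_patches)
from oracles import convlstm_step_literal


def random_params(rng, cin, hidden, spatial, k=3):
    p = ConvLSTMParams.zeros(cin, hidden, spatial, k)
    for name in vars(p):
        arr = getattr(p, name)
        setattr(p, name, rng.standard_normal(arr.shape).astype(np.float32) * 0.5)
    return p


# ---------------------------------------------------------------- encoder

@pytest.mark.parametrize("side,base,expected", [
    (256, 64, [(256, 256, 64), (128, 128, 128), (64, 64, 256), (32, 32, 512)]),
    (64, 8, [(64, 64, 8), (32, 32, 16), (16, 16, 32), (8, 8, 64)]),
])
def test_encoder_skip_shapes(side, base, expected):
    cfg = ModelConfig(input_side=side, base_filters=base,
                      convs_per_block=(1, 1, 1, 1), convlstm_grid=(2, 2))
    enc = build_encoder(cfg, np.random.default_rng(0))
    assert enc.skip_shapes() == expected
    x = nn.Tensor(np.zeros((1, side, side, 3), dtype=np.float32))
    skips = enc(x)
    assert [s.data.shape[1:] for s in skips] == expected


def test_indivisible_input_side_rejected():
    with pytest.raises(ConfigurationError):
        ModelConfig(input_side=100)
    with pytest.raises(ConfigurationError, match="level"):
        # divisible by 8 but the grid cannot tile the deepest skip map
        ModelConfig(input_side=24, convlstm_grid=(16, 16))


# ---------------------------------------------------------------- tiling

def test_split_examples(rng):
    x = rng.standard_normal((4, 4, 2)).astype(np.float32)
    patches = split_to_patches(x, (2, 2))
    assert len(patches) == 4 and patches[0].shape == (2, 2, 2)
    np.testing.assert_array_equal(patches[1], x[0:2, 2:4])  # row-major
    single = split_to_patches(x, (1, 1))
    np.testing.assert_array_equal(single[0], x)
    with pytest.raises(ValueError):
        split_to_patches(x, (3, 2))


@settings(max_examples=25, deadline=None)
@given(n=st.integers(1, 4), m=st.integers(1, 4),
       hp=st.integers(1, 3), wp=st.integers(1, 3), c=st.integers(1, 3),
       seed=st.integers(0, 10_000))
def test_split_reassemble_is_lossless(n, m, hp, wp, c, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n * hp, m * wp, c)).astype(np.float32)
    back = reassemble_patches(split_to_patches(x, (n, m)), (n, m))
    np.testing.assert_array_equal(back, x)


# ---------------------------------------------------------------- convLSTM

def test_convlstm_zero_params_closed_form(rng):
    params = ConvLSTMParams.zeros(cin=3, hidden=2, spatial=(4, 4))
    p = rng.standard_normal((4, 4, 3)).astype(np.float32)
    h, c = convlstm_step(p, None, params)
    np.testing.assert_array_equal(c, np.zeros((4, 4, 2)))
    np.testing.assert_array_equal(h, np.zeros((4, 4, 2)))


def test_convlstm_saturated_forget_gate_keeps_cell(rng):
    params = ConvLSTMParams.zeros(cin=2, hidden=2, spatial=(3, 3))
    params.b_f = params.b_f + 30.0     # forget gate ~ 1
    params.b_i = params.b_i - 30.0     # input gate ~ 0
    c_prev = rng.standard_normal((3, 3, 2)).astype(np.float32)
    h_prev = np.zeros_like(c_prev)
    p = rng.standard_normal((3, 3, 2)).astype(np.float32)
    _, c = convlstm_step(p, (h_prev, c_prev), params)
    np.testing.assert_allclose(c, c_prev, atol=1e-5)


@pytest.mark.parametrize("spatial,cin,hidden", [((1, 1), 1, 1), ((3, 3), 2, 2)])
def test_convlstm_step_matches_literal_oracle(spatial, cin, hidden):
    rng = np.random.default_rng(7)
    for trial in range(20):
        params = random_params(rng, cin, hidden, spatial)
        p = rng.standard_normal(spatial + (cin,)).astype(np.float32)
        h0 = rng.standard_normal(spatial + (hidden,)).astype(np.float32) * 0.5
        c0 = rng.standard_normal(spatial + (hidden,)).astype(np.float32) * 0.5
        h, c = convlstm_step(p, (h0, c0), params)
        h_ref, c_ref = convlstm_step_literal(
            p.astype(np.float64), h0.astype(np.float64),
            c0.astype(np.float64), params)
        np.testing.assert_allclose(h, h_ref, atol=1e-6)
        np.testing.assert_allclose(c, c_ref, atol=1e-6)


def test_gate_and_hidden_ranges(rng):
    """i, f, o in (0,1) and H in (-1,1) for random inputs."""
    params = random_params(rng, 2, 3, (4, 4))
    state = None
    for _ in range(5):
        p = rng.standard_normal((4, 4, 2)).astype(np.float32) * 2
        state = convlstm_step(p, state, params)
        h, _ = state
        assert (np.abs(h) < 1.0).all()


def test_fuse_matches_manual_composition(rng):
    params = random_params(rng, 6, 2, (2, 2))
    enc = rng.standard_normal((4, 4, 4)).astype(np.float32)
    dec = rng.standard_normal((4, 4, 2)).astype(np.float32)
    fused = convlstm_fuse(enc, dec, (2, 2), params)
    assert fused.shape == (4, 4, 2)
    cat = np.concatenate([enc, dec], axis=-1)
    state, outs = None, []
    for p in split_to_patches(cat, (2, 2)):
        state = convlstm_step(p, state, params)
        outs.append(state[0])
    np.testing.assert_allclose(fused, reassemble_patches(outs, (2, 2)),
                               atol=1e-6)


def test_fuse_grid_1x1_is_single_step(rng):
    params = random_params(rng, 4, 2, (4, 4))
    enc = rng.standard_normal((4, 4, 2)).astype(np.float32)
    dec = rng.standard_normal((4, 4, 2)).astype(np.float32)
    fused = convlstm_fuse(enc, dec, (1, 1), params)
    h, _ = convlstm_step(np.concatenate([enc, dec], axis=-1), None, params)
    np.testing.assert_allclose(fused, h, atol=1e-6)


def test_fuse_zero_params_zero_output(rng):
    params = ConvLSTMParams.zeros(4, 2, (2, 2))
    enc = rng.standard_normal((4, 4, 2)).astype(np.float32)
    dec = rng.standard_normal((4, 4, 2)).astype(np.float32)
    np.testing.assert_array_equal(convlstm_fuse(enc, dec, (2, 2), params),
                                  np.zeros((4, 4, 2)))


# ---------------------------------------------------------------- network

def test_forward_shape_range_and_determinism(tiny_model_config, rng):
    model = build_model(tiny_model_config)
    x = rng.uniform(size=(2, 32, 32, 3)).astype(np.float32)
    out1 = model.forward(x).data
    out2 = model.forward(x).data
    assert out1.shape == (2, 32, 32, 1)
    assert (out1 > 0).all() and (out1 < 1).all()
    np.testing.assert_array_equal(out1, out2)


def test_baseline_has_no_recurrent_weights(tiny_model_config):
    base = build_model(baseline_config(tiny_model_config))
    assert not base.is_recurrent
    assert not any("cell" in k for k in base.state_dict())
    full = build_model(tiny_model_config)
    assert any("cell" in k for k in full.state_dict())
    # recurrence adds parameters beyond the baseline's
    assert (sum(p.data.size for p in full.parameters())
            > sum(p.data.size for p in base.parameters()))


def test_save_load_round_trip(tiny_model_config, tmp_path, rng):
    model = build_model(tiny_model_config)
    x = rng.uniform(size=(1, 32, 32, 3)).astype(np.float32)
    before = model.forward(x).data
    model.save(tmp_path / "weights.npz")
    loaded = AKUNet.load(tmp_path / "weights.npz")
    np.testing.assert_array_equal(loaded.forward(x).data, before)
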