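"""Network family: module semantics, scalar-arithmetic oracles, shape and
normalisation invariants, controlled-ablation parameter sharing."""

import numpy as np
import pytest

from apexseg.arch import (Model, ModelSpec, SKConvSpec, TEBSpec, build_model,
                          init_params, sk_conv_forward, teb_forward,
                          unet_forward, variant_spec)
from apexseg.nn import Tensor
from apexseg.nn.tensor import logsumexp


def as_tensors(params):
    return {k: Tensor(v, requires_grad=True) for k, v in params.items()}


# -- spec validation -------------------------------------------------------

def test_skconv_spec_rejects_even_or_unsorted_kernels():
    with pytest.raises(ValueError):
        SKConvSpec(kernel_sizes=(1, 2, 3))
    with pytest.raises(ValueError):
        SKConvSpec(kernel_sizes=(3, 1))


def test_bottleneck_width_floor():
    spec = SKConvSpec(reduction_ratio=8, min_bottleneck=16)
    assert spec.bottleneck(8) == 16
    assert spec.bottleneck(256) == 32
    assert SKConvSpec(reduction_ratio=64, min_bottleneck=1).bottleneck(8) == 1


def test_named_variants_route_expected_skips():
    base = ModelSpec(depth=5)
    assert variant_spec("base", base).skip_modules == {}
    assert variant_spec("sk", base).skip_modules == \
        {1: "skconv", 2: "skconv", 3: "skconv"}
    assert variant_spec("teb", base).skip_modules == {4: "teb", 5: "teb"}
    assert variant_spec("improved", base).skip_modules == \
        {1: "skconv", 2: "skconv", 3: "skconv", 4: "teb", 5: "teb"}
    with pytest.raises(ValueError):
        variant_spec("bogus")


# -- SKConv ----------------------------------------------------------------

def _sk_setup(channels=2, size=8, kernels=(1, 3, 5, 7), seed=0):
    spec = SKConvSpec(kernel_sizes=kernels, reduction_ratio=2,
                      min_bottleneck=2)
    params = {}
    from apexseg.arch import _sk_params
    _sk_params(params, seed, "sk", channels, spec)
    rng = np.random.default_rng(seed + 100)
    x = rng.normal(size=(1, channels, size, size))
    return spec, params, x


def test_sk_equal_score_heads_average_branches():
    spec, params, x = _sk_setup()
    # identical per-branch rows in the select head -> equal scores
    w = params["sk.select.w"]
    c = x.shape[1]
    m = len(spec.kernel_sizes)
    w[:] = np.tile(w[:c], (m, 1))
    params["sk.select.b"][:] = np.tile(params["sk.select.b"][:c], m)
    out, weights = sk_conv_forward(Tensor(x), as_tensors(params), spec,
                                   prefix="sk", return_weights=True)
    np.testing.assert_allclose(weights.data, 1.0 / m)
    from apexseg.nn import conv2d
    pt = as_tensors(params)
    mean_branches = sum(
        conv2d(Tensor(x), pt[f"sk.branch{k}.w"], pt[f"sk.branch{k}.b"]).data
        for k in spec.kernel_sizes) / m
    np.testing.assert_allclose(out.data, mean_branches, rtol=1e-10)


def test_sk_single_kernel_reduces_to_plain_convolution():
    spec, params, x = _sk_setup(kernels=(1,))
    out, weights = sk_conv_forward(Tensor(x), as_tensors(params), spec,
                                   prefix="sk", return_weights=True)
    np.testing.assert_allclose(weights.data, 1.0)
    from apexseg.nn import conv2d
    pt = as_tensors(params)
    expected = conv2d(Tensor(x), pt["sk.branch1.w"], pt["sk.branch1.b"]).data
    np.testing.assert_allclose(out.data, expected, rtol=1e-12)


def test_sk_matches_scalar_arithmetic_oracle():
    """1-channel 3x3 input, tiny integer weights, hand-computed pipeline."""
    spec = SKConvSpec(kernel_sizes=(1, 3), reduction_ratio=1,
                      min_bottleneck=1)
    x = np.arange(9, dtype=float).reshape(1, 1, 3, 3)
    params = {
        "sk.branch1.w": np.full((1, 1, 1, 1), 2.0),
        "sk.branch1.b": np.array([1.0]),
        "sk.branch3.w": np.zeros((1, 1, 3, 3)),
        "sk.branch3.b": np.array([0.0]),
        "sk.reduce.w": np.array([[1.0]]),
        "sk.reduce.b": np.array([0.0]),
        "sk.select.w": np.array([[0.5], [-0.5]]),
        "sk.select.b": np.array([0.0, 0.0]),
    }
    params["sk.branch3.w"][0, 0, 1, 1] = 1.0   # centre tap = identity conv
    out = sk_conv_forward(Tensor(x), as_tensors(params), spec, prefix="sk")
    # scalar oracle
    b1 = 2.0 * x[0, 0] + 1.0
    b3 = x[0, 0]
    s = (b1 + b3).mean()
    z = max(s, 0.0)                      # reduce: weight 1, bias 0, relu
    e1, e2 = np.exp(0.5 * z), np.exp(-0.5 * z)
    w1, w2 = e1 / (e1 + e2), e2 / (e1 + e2)
    np.testing.assert_allclose(out.data[0, 0], w1 * b1 + w2 * b3, rtol=1e-10)


def test_sk_selection_weights_normalised_on_random_input(rng):
    spec, params, x = _sk_setup(channels=4, size=16, seed=3)
    out, weights = sk_conv_forward(Tensor(x), as_tensors(params), spec,
                                   prefix="sk", return_weights=True)
    assert out.shape == x.shape
    sums = weights.data.sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-5)
    assert (weights.data >= 0).all()


# -- TEB -------------------------------------------------------------------

def _teb_setup(channels=4, side=2, heads=1, depth=1, seed=0):
    spec = TEBSpec(num_heads=heads, mlp_ratio=2, depth=depth, patch_size=1)
    params = {}
    from apexseg.arch import _teb_params
    _teb_params(params, seed, "teb", channels, side * side, spec)
    rng = np.random.default_rng(seed + 7)
    x = rng.normal(size=(1, channels, side, side))
    return spec, params, x


def test_teb_preserves_shape_and_attention_rows_normalised():
    spec, params, x = _teb_setup(channels=8, side=4, heads=2, depth=2)
    out, atts = teb_forward(Tensor(x), as_tensors(params), spec,
                            prefix="teb", return_attention=True)
    assert out.shape == x.shape
    assert len(atts) == 2
    for att in atts:
        np.testing.assert_allclose(att.data.sum(axis=-1), 1.0, atol=1e-5)
        assert (att.data >= 0).all()


def test_teb_single_token_attention_is_value_projection():
    """With one token the attention weight is exactly 1."""
    spec, params, x = _teb_setup(channels=4, side=1, heads=2)
    out, atts = teb_forward(Tensor(x), as_tensors(params), spec,
                            prefix="teb", return_attention=True)
    np.testing.assert_allclose(atts[0].data, 1.0)
    assert out.shape == x.shape


def test_teb_matches_scalar_attention_oracle():
    """2x2 map, 1 head, hand-set projections vs scalar QK^T/sqrt(d) math."""
    spec, params, x = _teb_setup(channels=2, side=2, heads=1, depth=1)
    # zero position terms and identity layer norms simplify the oracle
    params["teb.pos"][:] = 0.0
    pt = as_tensors(params)
    out = teb_forward(Tensor(x), pt, spec, prefix="teb")

    # oracle with plain numpy scalar ops
    tok = x[0].reshape(2, 4).T                        # (T=4, E=2)
    def ln(v, g, b):
        mu, var = v.mean(), v.var()
        return (v - mu) / np.sqrt(var + 1e-5) * g + b
    def lin(v, w, b):
        return v @ w.T + b
    h1 = np.stack([ln(t, params["teb.blk0.ln1.g"], params["teb.blk0.ln1.b"])
                   for t in tok])
    q = lin(h1, params["teb.blk0.attn.wq.w"], params["teb.blk0.attn.wq.b"])
    k = lin(h1, params["teb.blk0.attn.wk.w"], params["teb.blk0.attn.wk.b"])
    v = lin(h1, params["teb.blk0.attn.wv.w"], params["teb.blk0.attn.wv.b"])
    scores = q @ k.T / np.sqrt(2.0)
    att = np.exp(scores - scores.max(axis=1, keepdims=True))
    att /= att.sum(axis=1, keepdims=True)
    y = lin(att @ v, params["teb.blk0.attn.wo.w"],
            params["teb.blk0.attn.wo.b"])
    tok2 = tok + y
    h2 = np.stack([ln(t, params["teb.blk0.ln2.g"], params["teb.blk0.ln2.b"])
                   for t in tok2])
    m = lin(np.maximum(lin(h2, params["teb.blk0.mlp.fc1.w"],
                           params["teb.blk0.mlp.fc1.b"]), 0.0),
            params["teb.blk0.mlp.fc2.w"], params["teb.blk0.mlp.fc2.b"])
    expected = (tok2 + m).T.reshape(1, 2, 2, 2)
    np.testing.assert_allclose(out.data, expected, rtol=1e-8, atol=1e-10)


def test_teb_forced_uniform_attention_broadcasts_mean_token():
    """Zero query/key projections force uniform attention; with a zeroed
    feed-forward the block reduces to input + the same attended mean at
    every position."""
    spec, params, x = _teb_setup(channels=2, side=2, heads=1, depth=1)
    params["teb.pos"][:] = 0.0
    for name in ("attn.wq", "attn.wk"):
        params[f"teb.blk0.{name}.w"][:] = 0.0
        params[f"teb.blk0.{name}.b"][:] = 0.0
    for name in ("mlp.fc1", "mlp.fc2"):
        params[f"teb.blk0.{name}.w"][:] = 0.0
        params[f"teb.blk0.{name}.b"][:] = 0.0
    out, atts = teb_forward(Tensor(x), as_tensors(params), spec,
                            prefix="teb", return_attention=True)
    np.testing.assert_allclose(atts[0].data, 0.25)
    # residual increment is identical across the four positions
    delta = (out.data - x)[0].reshape(2, -1)
    np.testing.assert_allclose(
        delta, np.broadcast_to(delta[:, :1], delta.shape), atol=1e-12)


def test_teb_rejects_indivisible_side():
    spec = TEBSpec(patch_size=2)
    params = {}
    from apexseg.arch import _teb_params
    _teb_params(params, 0, "teb", 4, 4, spec)
    with pytest.raises(ValueError):
        teb_forward(Tensor(np.zeros((1, 4, 3, 3))), as_tensors(params), spec,
                    prefix="teb")


# -- full model ------------------------------------------------------------

def test_forward_shape_contract():
    spec = variant_spec("improved", ModelSpec(base_channels=2))
    model = build_model(spec, seed=0, input_size=32)
    x = np.random.default_rng(0).normal(size=(2, 1, 32, 32))
    out = model.forward(model.tensors(False), Tensor(x))
    assert out.shape == (2, 4, 32, 32)


def test_indivisible_input_side_raises():
    spec = ModelSpec(depth=5, base_channels=2)
    model = build_model(spec, seed=0, input_size=32)
    with pytest.raises(ValueError):
        model.forward(model.tensors(False),
                      Tensor(np.zeros((1, 1, 40, 40))))
    with pytest.raises(ValueError):
        build_model(spec, seed=0, input_size=40)


def test_seeded_build_is_bit_reproducible():
    spec = variant_spec("improved", ModelSpec(base_channels=2))
    a = init_params(spec, seed=9, input_size=32)
    b = init_params(spec, seed=9, input_size=32)
    assert a.keys() == b.keys()
    for k in a:
        assert np.array_equal(a[k], b[k])
    c = init_params(spec, seed=10, input_size=32)
    assert any(not np.array_equal(a[k], c[k]) for k in a)


def test_variants_share_backbone_parameters_bit_identically():
    base_spec = ModelSpec(base_channels=2)
    models = {name: build_model(variant_spec(name, base_spec), seed=5,
                                input_size=32)
              for name in ("base", "sk", "teb", "improved")}
    shared = set(models["base"].params)
    for name in ("sk", "teb", "improved"):
        for k in shared & set(models[name].params):
            assert np.array_equal(models["base"].params[k],
                                  models[name].params[k]), (name, k)


def test_sk_variant_parameter_delta_matches_module_enumeration():
    base_spec = ModelSpec(base_channels=2)
    base = build_model(variant_spec("base", base_spec), 0, 32)
    sk = build_model(variant_spec("sk", base_spec), 0, 32)
    delta = sk.param_count() - base.param_count()
    # independent enumeration: three SK modules at levels 1..3
    expected = 0
    spec = base_spec.sk_spec
    for lvl in (1, 2, 3):
        c = base_spec.channels(lvl)
        d = spec.bottleneck(c)
        for k in spec.kernel_sizes:
            expected += c * c * k * k + c          # branch conv + bias
        expected += d * c + d                      # reduce
        expected += len(spec.kernel_sizes) * c * d \
            + len(spec.kernel_sizes) * c           # select heads
    assert delta == expected


def test_gradient_reaches_every_skip_module():
    spec = variant_spec("improved", ModelSpec(base_channels=2))
    model = build_model(spec, seed=1, input_size=32)
    x = np.random.default_rng(1).normal(size=(1, 1, 32, 32))
    pt = model.tensors(requires_grad=True)
    out = unet_forward(Tensor(x), pt, spec)
    loss = (out - logsumexp(out, axis=1, keepdims=True)).mean()
    loss.backward()
    for lvl, kind in spec.skip_modules.items():
        prefix = f"skip{lvl}."
        grads = [np.abs(t.grad).max() for k, t in pt.items()
                 if k.startswith(prefix) and t.grad is not None]
        assert grads and max(grads) > 0.0, (lvl, kind)
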