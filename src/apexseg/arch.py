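"""The improved-UNet network family.

The family is a 5-level encoder/decoder UNet whose skip connections can each
be routed through one of three modules:

``plain``
    identity pass-through (the classic UNet skip).
``skconv``
    selective-kernel convolution: parallel convolutions with kernels of
    several sizes (default 1, 3, 5, 7) are fused by summation, pooled
    globally, squeezed through a bottleneck, and re-weighted per channel by
    a softmax over branches before the weighted sum is emitted
    (split / fuse / select).  Used on the high-resolution skips where
    texture, not semantics, separates the anatomy.
``teb``
    transformer encoder block(s): the feature map is tokenised (patch size
    1 on the coarse maps), given learned position terms, and passed through
    pre-norm multi-head self-attention + feed-forward residual blocks.
    Used on the two coarsest connections where long-range context matters.

Both modules preserve the feature-map shape exactly, so they are drop-in
replacements for the plain skip, and the four named ablation variants
(``base``, ``sk``, ``teb``, ``improved``) differ only in the skip routing.
The coarsest "skip" of a depth-``d`` net is the bottleneck path itself: its
configured module transforms the bottleneck feature map in place before the
decoder starts.

Parameters are initialised per-name from a seed, so layers shared between
two variants built from the same seed start bit-identical (controlled
ablation).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .nn import (Tensor, concatenate, relu, softmax, layer_norm,
                 conv2d, conv_transpose2x2, maxpool2x2)

VARIANT_NAMES = ("base", "sk", "teb", "improved")


@dataclass(frozen=True)
class SKConvSpec:
    """Selective-kernel convolution hyper-parameters."""
    kernel_sizes: tuple = (1, 3, 5, 7)
    reduction_ratio: int = 8
    min_bottleneck: int = 16

    def __post_init__(self):
        ks = tuple(self.kernel_sizes)
        if any(k % 2 == 0 for k in ks):
            raise ValueError("kernel sizes must be odd")
        if list(ks) != sorted(set(ks)):
            raise ValueError("kernel sizes must be strictly increasing")
        object.__setattr__(self, "kernel_sizes", ks)

    def bottleneck(self, channels: int) -> int:
        return max(channels // self.reduction_ratio, self.min_bottleneck, 1)


@dataclass(frozen=True)
class TEBSpec:
    """Transformer-encoder-block hyper-parameters."""
    num_heads: int = 4
    mlp_ratio: int = 4
    depth: int = 2
    patch_size: int = 1


@dataclass(frozen=True)
class ModelSpec:
    """Complete description of one network variant."""
    depth: int = 5
    base_channels: int = 16
    num_classes: int = 4
    skip_modules: dict = field(default_factory=dict)  # level -> module name
    sk_spec: SKConvSpec = field(default_factory=SKConvSpec)
    teb_spec: TEBSpec = field(default_factory=TEBSpec)

    def __post_init__(self):
        for lvl, kind in self.skip_modules.items():
            if not 1 <= lvl <= self.depth:
                raise ValueError(f"skip level {lvl} outside 1..{self.depth}")
            if kind not in ("plain", "skconv", "teb"):
                raise ValueError(f"unknown skip module {kind!r}")

    def channels(self, level: int) -> int:
        return self.base_channels * 2 ** (level - 1)

    def skip_kind(self, level: int) -> str:
        return self.skip_modules.get(level, "plain")


def variant_spec(name: str, base: ModelSpec | None = None) -> ModelSpec:
    """The four named ablation variants over a common backbone."""
    base = base if base is not None else ModelSpec()
    d = base.depth
    sk_levels = {lvl: "skconv" for lvl in (1, 2, 3) if lvl <= d}
    teb_levels = {lvl: "teb" for lvl in (d - 1, d) if lvl >= 1}
    table = {
        "base": {},
        "sk": sk_levels,
        "teb": teb_levels,
        "improved": {**sk_levels, **teb_levels},
    }
    if name not in table:
        raise ValueError(f"unknown variant {name!r}; pick from {VARIANT_NAMES}")
    return replace(base, skip_modules=table[name])


# -- parameter initialisation ---------------------------------------------

def _rng_for(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _he(rng, shape, fan_in):
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def _conv_param(params, seed, name, cout, cin, k):
    rng = _rng_for(seed, name)
    params[name + ".w"] = _he(rng, (cout, cin, k, k), cin * k * k)
    params[name + ".b"] = np.zeros(cout)


def _fc_param(params, seed, name, nout, nin):
    rng = _rng_for(seed, name)
    params[name + ".w"] = _he(rng, (nout, nin), nin)
    params[name + ".b"] = np.zeros(nout)


def _sk_params(params, seed, prefix, channels, spec: SKConvSpec):
    for k in spec.kernel_sizes:
        _conv_param(params, seed, f"{prefix}.branch{k}", channels, channels, k)
    d = spec.bottleneck(channels)
    _fc_param(params, seed, f"{prefix}.reduce", d, channels)
    _fc_param(params, seed, f"{prefix}.select",
              len(spec.kernel_sizes) * channels, d)


def _teb_params(params, seed, prefix, channels, tokens, spec: TEBSpec):
    emb = channels * spec.patch_size ** 2
    if emb % spec.num_heads:
        raise ValueError(
            f"embedding width {emb} not divisible by {spec.num_heads} heads")
    rng = _rng_for(seed, prefix + ".pos")
    params[prefix + ".pos"] = rng.normal(0.0, 0.02, size=(tokens, emb))
    for i in range(spec.depth):
        blk = f"{prefix}.blk{i}"
        for ln in ("ln1", "ln2"):
            params[f"{blk}.{ln}.g"] = np.ones(emb)
            params[f"{blk}.{ln}.b"] = np.zeros(emb)
        for proj in ("wq", "wk", "wv", "wo"):
            _fc_param(params, seed, f"{blk}.attn.{proj}", emb, emb)
        _fc_param(params, seed, f"{blk}.mlp.fc1", spec.mlp_ratio * emb, emb)
        _fc_param(params, seed, f"{blk}.mlp.fc2", emb, spec.mlp_ratio * emb)


# -- forward passes --------------------------------------------------------

def _linear(x: Tensor, params, name: str) -> Tensor:
    return x @ params[name + ".w"].transpose(1, 0) + params[name + ".b"]


def sk_conv_forward(x: Tensor, params: dict, spec: SKConvSpec,
                    prefix: str = "sk", return_weights: bool = False):
    """Split / fuse / select over multi-size convolution branches.

    ``x``: (N,C,H,W) -> (N,C,H,W).  Selection weights are a softmax over
    branches per (sample, channel), so they are nonnegative and sum to 1.
    """
    branches = [conv2d(x, params[f"{prefix}.branch{k}.w"],
                       params[f"{prefix}.branch{k}.b"])
                for k in spec.kernel_sizes]
    fused = branches[0]
    for b in branches[1:]:
        fused = fused + b
    s = fused.mean(axis=(2, 3))                       # (N, C) global pool
    z = relu(_linear(s, params, f"{prefix}.reduce"))  # (N, d)
    scores = _linear(z, params, f"{prefix}.select")   # (N, M*C)
    n, c = x.shape[0], x.shape[1]
    m = len(spec.kernel_sizes)
    weights = softmax(scores.reshape(n, m, c), axis=1)  # (N, M, C)
    stack = concatenate([b.reshape(n, 1, c, x.shape[2], x.shape[3])
                         for b in branches], axis=1)    # (N, M, C, H, W)
    out = (stack * weights.reshape(n, m, c, 1, 1)).sum(axis=1)
    if return_weights:
        return out, weights
    return out


def _mhsa(x: Tensor, params, prefix: str, num_heads: int,
          return_attention: bool = False):
    """Multi-head self-attention over (N, T, E) token stacks."""
    n, t, e = x.shape
    hd = e // num_heads

    def split_heads(y):
        return y.reshape(n, t, num_heads, hd).transpose(0, 2, 1, 3)

    q = split_heads(_linear(x, params, prefix + ".wq"))
    k = split_heads(_linear(x, params, prefix + ".wk"))
    v = split_heads(_linear(x, params, prefix + ".wv"))
    att = softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd)),
                  axis=-1)                            # (N, H, T, T)
    y = (att @ v).transpose(0, 2, 1, 3).reshape(n, t, e)
    out = _linear(y, params, prefix + ".wo")
    if return_attention:
        return out, att
    return out


def teb_forward(x: Tensor, params: dict, spec: TEBSpec,
                prefix: str = "teb", return_attention: bool = False):
    """Tokenise, run transformer encoder blocks, reassemble.

    ``x``: (N,C,H,W) -> (N,C,H,W); H and W must be divisible by patch_size.
    """
    n, c, h, w = x.shape
    p = spec.patch_size
    if h % p or w % p:
        raise ValueError(f"spatial side ({h},{w}) not divisible by patch {p}")
    gh, gw = h // p, w // p
    tokens = gh * gw
    emb = c * p * p
    # (N,C,gh,p,gw,p) -> (N, gh*gw, C*p*p)
    tok = x.reshape(n, c, gh, p, gw, p).transpose(0, 2, 4, 1, 3, 5) \
        .reshape(n, tokens, emb)
    tok = tok + params[prefix + ".pos"]
    attentions = []
    for i in range(spec.depth):
        blk = f"{prefix}.blk{i}"
        h1 = layer_norm(tok, params[f"{blk}.ln1.g"], params[f"{blk}.ln1.b"])
        a, att = _mhsa(h1, params, f"{blk}.attn", spec.num_heads,
                       return_attention=True)
        attentions.append(att)
        tok = tok + a
        h2 = layer_norm(tok, params[f"{blk}.ln2.g"], params[f"{blk}.ln2.b"])
        m = _linear(relu(_linear(h2, params, f"{blk}.mlp.fc1")),
                    params, f"{blk}.mlp.fc2")
        tok = tok + m
    out = tok.reshape(n, gh, gw, c, p, p).transpose(0, 3, 1, 4, 2, 5) \
        .reshape(n, c, h, w)
    if return_attention:
        return out, attentions
    return out


# -- the full network ------------------------------------------------------

@dataclass
class Model:
    """A built network: spec + named parameter arrays + forward pass."""
    spec: ModelSpec
    params: dict
    seed: int
    input_size: int | None = None  # side the TEB position terms were sized for

    def param_count(self, prefix: str = "") -> int:
        return sum(v.size for k, v in self.params.items()
                   if k.startswith(prefix))

    def tensors(self, requires_grad: bool = False) -> dict:
        return {k: Tensor(v, requires_grad=requires_grad)
                for k, v in self.params.items()}

    def forward(self, params: dict, x: Tensor) -> Tensor:
        return unet_forward(x, params, self.spec)


def init_params(spec: ModelSpec, seed: int, input_size: int = 64) -> dict:
    """Deterministic per-name initialisation of every parameter array.

    ``input_size`` fixes the token count of any TEB skip (position terms
    are learned per token).
    """
    if input_size % 2 ** (spec.depth - 1):
        raise ValueError(
            f"input side {input_size} not divisible by 2^{spec.depth - 1}")
    params: dict = {}
    d = spec.depth
    for lvl in range(1, d + 1):
        cin = 1 if lvl == 1 else spec.channels(lvl - 1)
        c = spec.channels(lvl)
        _conv_param(params, seed, f"enc{lvl}.conv1", c, cin, 3)
        _conv_param(params, seed, f"enc{lvl}.conv2", c, c, 3)
        kind = spec.skip_kind(lvl)
        if kind == "skconv":
            _sk_params(params, seed, f"skip{lvl}.sk", c, spec.sk_spec)
        elif kind == "teb":
            side = input_size // 2 ** (lvl - 1)
            tokens = (side // spec.teb_spec.patch_size) ** 2
            _teb_params(params, seed, f"skip{lvl}.teb", c, tokens,
                        spec.teb_spec)
    for lvl in range(d - 1, 0, -1):
        c = spec.channels(lvl)
        rng = _rng_for(seed, f"dec{lvl}.up")
        params[f"dec{lvl}.up.w"] = _he(rng, (2 * c, c, 2, 2), 2 * c * 4)
        params[f"dec{lvl}.up.b"] = np.zeros(c)
        _conv_param(params, seed, f"dec{lvl}.conv1", c, 2 * c, 3)
        _conv_param(params, seed, f"dec{lvl}.conv2", c, c, 3)
    _conv_param(params, seed, "head", spec.num_classes, spec.base_channels, 1)
    return params


def build_model(spec: ModelSpec, seed: int, input_size: int = 64) -> Model:
    return Model(spec=spec, params=init_params(spec, seed, input_size),
                 seed=seed, input_size=input_size)


def _double_conv(x: Tensor, params, name: str) -> Tensor:
    x = relu(conv2d(x, params[f"{name}.conv1.w"], params[f"{name}.conv1.b"]))
    return relu(conv2d(x, params[f"{name}.conv2.w"], params[f"{name}.conv2.b"]))


def _skip(x: Tensor, params, spec: ModelSpec, level: int) -> Tensor:
    kind = spec.skip_kind(level)
    if kind == "plain":
        return x
    if kind == "skconv":
        return sk_conv_forward(x, params, spec.sk_spec,
                               prefix=f"skip{level}.sk")
    return teb_forward(x, params, spec.teb_spec, prefix=f"skip{level}.teb")


def unet_forward(x: Tensor, params: dict, spec: ModelSpec) -> Tensor:
    """(N,1,H,W) image batch -> (N,num_classes,H,W) score map."""
    side = x.shape[2]
    if side % 2 ** (spec.depth - 1) or x.shape[3] % 2 ** (spec.depth - 1):
        raise ValueError(
            f"input side {x.shape[2:]} not divisible by 2^{spec.depth - 1}")
    feats = []
    h = x
    for lvl in range(1, spec.depth + 1):
        if lvl > 1:
            h = maxpool2x2(h)
        h = _double_conv(h, params, f"enc{lvl}")
        feats.append(h)
    h = _skip(feats[-1], params, spec, spec.depth)   # bottleneck connection
    for lvl in range(spec.depth - 1, 0, -1):
        h = conv_transpose2x2(h, params[f"dec{lvl}.up.w"],
                              params[f"dec{lvl}.up.b"])
        skip = _skip(feats[lvl - 1], params, spec, lvl)
        h = concatenate([skip, h], axis=1)
        h = _double_conv(h, params, f"dec{lvl}")
    return conv2d(h, params["head.w"], params["head.b"], padding=0)
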