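"""Network architectures: U-Net generator and patch discriminator.

The generator is an encoder/decoder U-Net whose decoder uses
resize-convolutions (nearest-neighbour upsampling followed by an ordinary
convolution) instead of transposed convolutions; transposed convolutions
tile the output with a checkerboard pattern that is fatal when the target
is a single-pixel localization map.  The discriminator is a PatchGAN: a
small fully-convolutional net scoring overlapping patches, which makes the
adversarial loss independent of the frame size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["GeneratorSpec", "DiscriminatorSpec", "UNetGenerator", "PatchDiscriminator"]


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator hyper-parameters.

    depth is the number of encoder (and decoder) stages, each halving
    (doubling) the grid; the input must be divisible by ``2**depth``.
    ``noise_mode`` enables dropout in the decoder, the conventional
    realization of the GAN noise input.
    """

    depth: int = 3
    base_channels: int = 16
    upsampling: str = "resize_convolution"
    noise_mode: bool = False
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.upsampling != "resize_convolution":
            raise ValueError("only resize_convolution upsampling is supported")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN discriminator hyper-parameters."""

    n_layers: int = 2
    base_channels: int = 16

    @property
    def patch_receptive_field(self) -> int:
        # stack of n stride-2 4x4 convs plus a 3x3 head
        rf = 3
        for _ in range(self.n_layers):
            rf = rf * 2 + 2
        return rf


def _he_init(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _Conv:
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int,
                 k: int, stride: int, pad: int):
        self.w = Tensor(_he_init(rng, (c_out, c_in, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class UNetGenerator:
    """Fully convolutional U-Net mapping frames to localization maps.

    The output head is linear; the sparsity term of the training loss pulls
    the background to zero and inference clips residual negatives.  Any
    input whose sides are divisible by ``2**depth`` is accepted,
    independent of the training size.
    """

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        cmax = 8 * spec.base_channels
        enc_ch = [min(spec.base_channels * 2**i, cmax) for i in range(spec.depth)]
        self.encoders = []
        c_prev = 1
        for c in enc_ch:
            self.encoders.append(_Conv(rng, c_prev, c, k=4, stride=2, pad=1))
            c_prev = c
        self.decoders = []
        cur = enc_ch[-1]
        for i in range(spec.depth):
            skip = enc_ch[spec.depth - 2 - i] if i < spec.depth - 1 else 1
            out = enc_ch[spec.depth - 2 - i] if i < spec.depth - 1 else spec.base_channels
            # resize-convolution: upsample happens in forward(), then this conv
            self.decoders.append(_Conv(rng, cur + skip, out, k=3, stride=1, pad=1))
            cur = out
        self.head = _Conv(rng, cur, 1, k=3, stride=1, pad=1)
        self._dropout_rng = np.random.default_rng(seed + 1)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for m in (*self.encoders, *self.decoders, self.head):
            ps.extend(m.params)
        return ps

    def forward(self, x: Tensor, train: bool = False) -> Tensor:
        d = self.spec.depth
        h, w = x.shape[2], x.shape[3]
        if h % 2**d or w % 2**d:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2**depth = {2**d}"
            )
        feats = []
        hcur = x
        for enc in self.encoders:
            hcur = ag.leaky_relu(enc(hcur), 0.2)
            feats.append(hcur)
        for i, dec in enumerate(self.decoders):
            hcur = ag.upsample_nearest(hcur, 2)
            skip = feats[d - 2 - i] if i < d - 1 else x
            hcur = ag.concat_channels(hcur, skip)
            hcur = ag.relu(dec(hcur))
            if self.spec.noise_mode:
                hcur = ag.dropout(hcur, self.spec.dropout_p, self._dropout_rng,
                                  active=train or self.spec.noise_mode)
        # linear head: the targets are sparse, so with a saturating
        # non-negativity activation (ReLU or softplus) the background
        # gradient drives pre-activations deeply negative early in training
        # and the map collapses to zero with no usable gradient to recover.
        # A linear output keeps the L1 subgradient bounded everywhere;
        # negatives are clipped at inference instead.
        return self.head(hcur)

    __call__ = forward

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.encoders):
            out[f"enc{i}.w"], out[f"enc{i}.b"] = m.w.data, m.b.data
        for i, m in enumerate(self.decoders):
            out[f"dec{i}.w"], out[f"dec{i}.b"] = m.w.data, m.b.data
        out["head.w"], out["head.b"] = self.head.w.data, self.head.b.data
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.encoders):
            m.w.data, m.b.data = sd[f"enc{i}.w"].copy(), sd[f"enc{i}.b"].copy()
        for i, m in enumerate(self.decoders):
            m.w.data, m.b.data = sd[f"dec{i}.w"].copy(), sd[f"dec{i}.b"].copy()
        self.head.w.data, self.head.b.data = sd["head.w"].copy(), sd["head.b"].copy()


class PatchDiscriminator:
    """Convolutional patch classifier on (frame, map) channel pairs.

    Outputs a grid of per-patch probabilities in (0, 1).
    """

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.layers = []
        c_prev = 2
        c = spec.base_channels
        for _ in range(spec.n_layers):
            self.layers.append(_Conv(rng, c_prev, c, k=4, stride=2, pad=1))
            c_prev, c = c, min(2 * c, 8 * spec.base_channels)
        self.head = _Conv(rng, c_prev, 1, k=3, stride=1, pad=1)

    @property
    def params(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for m in (*self.layers, self.head):
            ps.extend(m.params)
        return ps

    def forward(self, x: Tensor, y: Tensor) -> Tensor:
        h = ag.concat_channels(x, y)
        for layer in self.layers:
            h = ag.leaky_relu(layer(h), 0.2)
        return ag.sigmoid(self.head(h))

    __call__ = forward

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.layers):
            out[f"d{i}.w"], out[f"d{i}.b"] = m.w.data, m.b.data
        out["dhead.w"], out["dhead.b"] = self.head.w.data, self.head.b.data
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.layers):
            m.w.data, m.b.data = sd[f"d{i}.w"].copy(), sd[f"d{i}.b"].copy()
        self.head.w.data, self.head.b.data = sd["dhead.w"].copy(), sd["dhead.b"].copy()
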