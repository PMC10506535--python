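"""Network building blocks: a modified U-Net generator, multi-scale patch
discriminators, and a fixed convolutional feature extractor for the
perceptual loss.

All parameters are seeded at construction, so two modules built from the
same spec are bit-identical — the reproducibility contract the training
loops rely on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import (
    Tensor,
    avg_pool2d,
    concat,
    conv2d,
    upsample_nearest2x,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "Module",
    "Conv2d",
    "InstanceNorm2d",
    "UNetGenerator",
    "PatchDiscriminator",
    "MultiScaleDiscriminator",
    "FeatureExtractor",
    "build_generator",
    "build_discriminators",
]


@dataclass
class GeneratorSpec:
    """Shape of the image-to-image generator.

    ``in_channels`` is 7 for the SRS→H&E stainer (one per Raman band) and 3
    for the H&E-domain translators; outputs are always 3-channel RGB in
    [0, 1].
    """

    in_channels: int = 7
    out_channels: int = 3
    base_width: int = 16
    depth: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class DiscriminatorSpec:
    """Shape of one patch discriminator; it is always instantiated twice,
    once per image scale (full resolution and 2x average-pooled)."""

    in_channels: int = 3
    layers: int = 3
    base_width: int = 16
    scales: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.scales != 2:
            raise ValueError("multi-scale discriminator is defined for exactly 2 scales")


class Module:
    """Minimal parameter container."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def checksum(self) -> str:
        """SHA-256 over all parameter bytes, in parameter order."""
        h = hashlib.sha256()
        for p in self.parameters():
            h.update(np.ascontiguousarray(p.data).tobytes())
        return h.hexdigest()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state array count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = a.astype(p.data.dtype, copy=True)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=3, stride=1, padding=1,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))  # He init for (leaky) ReLU
        self.weight = Tensor(
            (rng.standard_normal((c_out, c_in, kernel, kernel)) * scale).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization with learnable affine."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        return xc / (var + self.eps) ** 0.5 * self.gamma + self.beta


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, rng, dtype, norm=True, slope=0.2):
        self.conv = Conv2d(c_in, c_out, rng=rng, dtype=dtype)
        self.norm = InstanceNorm2d(c_out, dtype=dtype) if norm else None
        self.slope = slope

    def __call__(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        if self.norm is not None:
            y = self.norm(y)
        return y.leaky_relu(self.slope)


class UNetGenerator(Module):
    """Encoder–decoder with skip connections at every level.

    Downsampling is 2x average pooling, upsampling nearest-neighbour; the
    final 1x1 convolution is squashed through a sigmoid so outputs always
    land in [0, 1]^3 regardless of input scale.
    """

    def __init__(self, spec: GeneratorSpec, dtype=np.float32):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.base_width
        self.enc = []
        c = spec.in_channels
        for level in range(spec.depth):
            width = w * 2**level
            self.enc.append(_ConvBlock(c, width, rng, dtype, norm=level > 0))
            c = width
        self.bottleneck = _ConvBlock(c, c * 2, rng, dtype)
        self.dec = []
        c_up = c * 2
        for level in reversed(range(spec.depth)):
            width = w * 2**level
            # after upsample, concat with the skip of the same width
            self.dec.append(_ConvBlock(c_up + width, width, rng, dtype))
            c_up = width
        self.head = Conv2d(c_up, spec.out_channels, kernel=1, padding=0, rng=rng, dtype=dtype)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        div = 2**self.spec.depth
        if h % div or w % div:
            pad_h = (div - h % div) % div
            pad_w = (div - w % div) % div
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={div}; "
                f"pad by ({pad_h}, {pad_w}) first"
            )
        skips = []
        y = x
        for block in self.enc:
            y = block(y)
            skips.append(y)
            y = avg_pool2d(y, 2)
        y = self.bottleneck(y)
        for block, skip in zip(self.dec, reversed(skips)):
            y = upsample_nearest2x(y)
            y = block(concat([y, skip], axis=1))
        return self.head(y).sigmoid()


class PatchDiscriminator(Module):
    """Stride-2 conv stack emitting a spatial map of realism scores."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.blocks = []
        c = spec.in_channels
        width = spec.base_width
        for i in range(spec.layers):
            self.blocks.append(
                _ConvBlock(c, width, rng, dtype, norm=i > 0)
            )
            c = width
            width = min(width * 2, 8 * spec.base_width)
        self.head = Conv2d(c, 1, kernel=1, padding=0, rng=rng, dtype=dtype)
        self.min_input = 2**spec.layers

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h < self.min_input or w < self.min_input:
            raise ValueError(
                f"input {h}x{w} smaller than the discriminator receptive field "
                f"({self.min_input})"
            )
        y = x
        for block in self.blocks:
            y = block(y)
            y = avg_pool2d(y, 2)
        return self.head(y)


class MultiScaleDiscriminator(Module):
    """Two identically-initialized patch discriminators; the second always
    scores the 2x average-pooled input."""

    def __init__(self, spec: DiscriminatorSpec, dtype=np.float32):
        self.spec = spec
        # identical layouts AND identical initial weights: same seed stream
        self.d_full = PatchDiscriminator(spec, np.random.default_rng(spec.seed), dtype)
        self.d_half = PatchDiscriminator(spec, np.random.default_rng(spec.seed), dtype)

    def __call__(self, x: Tensor) -> list[Tensor]:
        return [self.d_full(x), self.d_half(avg_pool2d(x, 2))]


class FeatureExtractor(Module):
    """Fixed (never-trained) convolutional feature maps for the perceptual
    loss.

    Provenance ``random_seeded`` draws a small conv stack from a seed;
    ``pretrained_vgg19`` loads conv weights from an ``.npz`` the user supplies
    (taps after each stage).  Either way the parameters are frozen.
    """

    def __init__(self, in_channels: int = 3, widths=(8, 16, 32), seed: int = 0,
                 provenance: str = "random_seeded", weights_path: str | None = None,
                 dtype=np.float32):
        if provenance not in ("random_seeded", "pretrained_vgg19"):
            raise ValueError(f"unknown provenance {provenance!r}")
        self.provenance = provenance
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stages = []
        c = in_channels
        if provenance == "pretrained_vgg19":
            if weights_path is None:
                raise ValueError("pretrained_vgg19 provenance requires weights_path")
            arrays = np.load(weights_path)
            names = sorted(arrays.files)
            for name in names:
                wdata = arrays[name]
                stage = Conv2d(wdata.shape[1], wdata.shape[0], kernel=wdata.shape[2],
                               padding=wdata.shape[2] // 2, dtype=dtype)
                stage.weight.data = wdata.astype(dtype)
                self.stages.append(stage)
        else:
            for width in widths:
                self.stages.append(Conv2d(c, width, rng=rng, dtype=dtype))
                c = width
        for p in self.parameters():
            p.requires_grad = False  # frozen by contract

    def __call__(self, x: Tensor) -> list[Tensor]:
        taps = []
        y = x
        for i, stage in enumerate(self.stages):
            y = stage(y).leaky_relu(0.2)
            taps.append(y)
            if i < len(self.stages) - 1 and y.shape[2] % 2 == 0 and y.shape[3] % 2 == 0:
                y = avg_pool2d(y, 2)
        return taps


def build_generator(spec: GeneratorSpec, dtype=np.float32) -> UNetGenerator:
    return UNetGenerator(spec, dtype=dtype)


def build_discriminators(spec: DiscriminatorSpec, dtype=np.float32) -> MultiScaleDiscriminator:
    return MultiScaleDiscriminator(spec, dtype=dtype)
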