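"""ConvNeXt-style convolutional sequence encoder with stage splicing.

The encoder treats a character sequence as an image-like map of height 1
and width L.  It applies a stem convolution (kernel 4, stride 1), four
stages of inverted-bottleneck blocks stacked 3:3:9:3 with channel widths
128/256/512/1024 by default, a layer-norm + kernel-2 stride-1
convolution downsampling layer between stages, and finally concatenates
("splices") the output of every stage along the channel axis, giving
L x (128+256+512+1024) = L x 1920 features at the defaults.

Every operator is stride 1 with zero padding, so sequence length is
preserved end to end.  Each block is: depthwise convolution (per-channel
filtering, parameter count Dk*Dk*1*M) -> layer normalisation -> 1x1
convolution expanding channels 4x -> GELU -> 1x1 convolution back ->
residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special as _sp

from .autograd import Tensor, concat
from .nn import Linear, LayerNorm, Module, Parameter, glorot

__all__ = [
    "FeatureMap", "ConvStageConfig", "gelu", "layer_norm",
    "DepthwiseConv", "Conv1d", "ConvBlock", "DownsampleLayer", "ConvEncoder",
    "count_parameters",
]


@dataclass
class FeatureMap:
    """A sequence of feature vectors: (L, C) or height-1 (1, L, C) values
    with a length-L validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be (L, C) or (1, L, C)")
        L = self.values.shape[-2]
        if self.mask.shape != (L,):
            raise ValueError("mask length must equal sequence length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")

    @property
    def length(self) -> int:
        return self.values.shape[-2]

    @property
    def channels(self) -> int:
        return self.values.shape[-1]


def gelu(x):
    """Exact Gaussian-error linear unit: x * Phi(x) = x * (1 + erf(x/sqrt 2)) / 2.

    Accepts a numpy array (returns an array) or an autograd Tensor
    (returns a Tensor with the exact-erf gradient).
    """
    if isinstance(x, Tensor):
        return x.gelu()
    x = np.asarray(x, dtype=np.float64)
    return x * 0.5 * (1.0 + _sp.erf(x / np.sqrt(2.0)))


def layer_norm(x, eps: float = 1e-6):
    """Pre-affine layer normalisation over the channel (last) axis.

    Per position: (x - E[x]) / sqrt(Var[x] + eps) with the biased 1/n
    variance.  Normalises the channels of a single sample, not a batch.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


@dataclass
class ConvStageConfig:
    """Architecture of the convolutional encoder; defaults are the
    reference configuration (stack ratio 3:3:9:3, channels
    128/256/512/1024, stem kernel 4 stride 1, downsample kernel 2
    stride 1)."""

    depths: tuple[int, ...] = (3, 3, 9, 3)
    channels: tuple[int, ...] = (128, 256, 512, 1024)
    stem_kernel: int = 4
    stem_stride: int = 1
    block_dw_kernel: int = 7
    expansion: int = 4
    downsample_kernel: int = 2
    downsample_stride: int = 1
    ln_eps: float = 1e-6

    def __post_init__(self):
        if len(self.depths) != len(self.channels):
            raise ValueError("depths and channels must have equal length")
        if any(d < 0 for d in self.depths) or any(c <= 0 for c in self.channels):
            raise ValueError("depths must be >= 0 and channels positive")
        if self.stem_stride != 1 or self.downsample_stride != 1:
            raise ValueError("all strides are 1 (sequence length is preserved)")
        if self.block_dw_kernel % 2 != 1:
            raise ValueError("block_dw_kernel must be odd")
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")

    @property
    def out_channels(self) -> int:
        """Width after splicing the stage outputs.

        Stages with zero blocks do not participate in the splice; a
        fully empty stack degenerates to the stem output alone.
        """
        active = [c for d, c in zip(self.depths, self.channels) if d > 0]
        return int(sum(active)) if active else int(self.channels[0])

    @property
    def n_blocks(self) -> int:
        return int(sum(self.depths))


def _pad_lr(k: int) -> tuple[int, int]:
    # symmetric for odd kernels, one-sided (right) for even kernels
    if k % 2 == 1:
        return k // 2, k // 2
    return 0, k - 1


class Conv1d(Module):
    """Stride-1 sequence convolution mapping C_in -> C_out channels.

    Length is preserved by zero padding (symmetric for odd kernels,
    right-sided for even ones, e.g. the stem's kernel 4 and the
    downsampling layers' kernel 2).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = int(kernel)
        self.weight = Parameter(glorot(rng, kernel * c_in, c_out,
                                       shape=(kernel, c_in, c_out)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[1]
        left, right = _pad_lr(self.kernel)
        xp = x.pad_length(left, right)
        out = None
        for j in range(self.kernel):
            term = xp[:, j:j + L, :] @ self.weight[j]
            out = term if out is None else out + term
        return out + self.bias


class DepthwiseConv(Module):
    """Per-channel convolution: channel c of the output depends only on
    channel c of the input.

    Kernels are stored as full Dk x Dk x M tensors acting on the
    height-1 map; with symmetric zero padding on the singleton height
    axis only the centre row reaches the data, so the layer behaves as a
    1-D convolution while carrying the Dk*Dk*1*M parameters of its 2-D
    form (1/N of a standard convolution's Dk*Dk*M*N).
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("depthwise kernel must be odd")
        self.kernel = int(kernel)
        self.channels = int(channels)
        scale = 1.0 / np.sqrt(kernel)
        self.weight = Parameter(rng.uniform(-scale, scale,
                                            size=(kernel, kernel, channels)))
        self.bias = Parameter(np.zeros(channels))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"depthwise conv expects {self.channels} channels, got {x.shape[-1]}")
        L = x.shape[1]
        half = self.kernel // 2
        xp = x.pad_length(half, half)
        w_eff = self.weight[half]  # centre row, (Dk, C)
        out = None
        for j in range(self.kernel):
            term = xp[:, j:j + L, :] * w_eff[j]
            out = term if out is None else out + term
        return out + self.bias


class ConvBlock(Module):
    """Inverted-bottleneck residual block:
    depthwise conv -> LN -> 1x1 conv (C -> e*C) -> GELU -> 1x1 conv
    (e*C -> C) -> + input."""

    def __init__(self, channels: int, cfg: ConvStageConfig, rng: np.random.Generator):
        self.dw = DepthwiseConv(channels, cfg.block_dw_kernel, rng)
        self.norm = LayerNorm(channels, cfg.ln_eps)
        self.pw1 = Linear(channels, cfg.expansion * channels, rng)
        self.pw2 = Linear(cfg.expansion * channels, channels, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.dw(x)
        h = self.norm(h)
        h = self.pw1(h)
        h = h.gelu()
        h = self.pw2(h)
        return x + h


class DownsampleLayer(Module):
    """Between-stage layer: layer normalisation followed by a kernel-2
    stride-1 convolution that widens the channels; length is unchanged."""

    def __init__(self, c_in: int, c_out: int, cfg: ConvStageConfig, rng: np.random.Generator):
        self.norm = LayerNorm(c_in, cfg.ln_eps)
        self.conv = Conv1d(c_in, c_out, cfg.downsample_kernel, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(self.norm(x))


class ConvEncoder(Module):
    """The full convolutional feature extractor with stage splicing.

    Forward: stem (kernel 4, stride 1 -> channels[0], then LN), stage 1
    blocks, downsample, stage 2, downsample, stage 3, downsample,
    stage 4; the last map of every stage is recorded and the four are
    concatenated along channels.  Masked (padding) positions are zeroed
    after every layer so padding never leaks into real positions.
    """

    def __init__(self, in_channels: int, cfg: ConvStageConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.in_channels = int(in_channels)
        self.stem = Conv1d(in_channels, cfg.channels[0], cfg.stem_kernel, rng)
        self.stem_norm = LayerNorm(cfg.channels[0], cfg.ln_eps)
        self.stages = [[ConvBlock(c, cfg, rng) for _ in range(d)]
                       for d, c in zip(cfg.depths, cfg.channels)]
        # a downsample into stage i+1 only exists if a later stage has blocks
        self.downsamples = [
            (DownsampleLayer(cfg.channels[i], cfg.channels[i + 1], cfg, rng)
             if any(d > 0 for d in cfg.depths[i + 1:]) else None)
            for i in range(len(cfg.channels) - 1)
        ]

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        """(B, L, in_channels) + (B, L) mask -> (B, L, out_channels)."""
        m = Tensor(np.asarray(mask, dtype=np.float64)[:, :, None])
        x = x * m  # padding must not reach real positions through conv windows
        h = self.stem_norm(self.stem(x)) * m
        outs = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                h = blk(h) * m
            if blocks:
                outs.append(h)
            if i < len(self.downsamples) and self.downsamples[i] is not None:
                h = self.downsamples[i](h) * m
        if not outs:  # fully empty stack: the stem output is the feature map
            outs = [h]
        return concat(outs, axis=-1)

    def encode(self, fm: FeatureMap) -> FeatureMap:
        """Single-sentence convenience over :class:`FeatureMap`.

        Accepts the height-1 (1, L, C) map produced by the embedding
        expansion (or a plain (L, C) map) and returns (L, sum(channels)).
        """
        v = fm.values
        if v.ndim == 2:
            v = v[np.newaxis]
        out = self(Tensor(v), fm.mask[np.newaxis, :])
        return FeatureMap(out.data[0], fm.mask.copy())


def count_parameters(cfg: ConvStageConfig, in_channels: int) -> int:
    """Closed-form parameter count of :class:`ConvEncoder`.

    stem: k*C_in*C0 + C0 bias, + 2*C0 for its LN;
    each block at width C: Dk*Dk*1*C depthwise weights + C bias,
    2*C LN affine, C*(e*C) + e*C and (e*C)*C + C pointwise;
    each downsample C_i -> C_{i+1}: 2*C_i LN + k*C_i*C_{i+1} + C_{i+1}.
    Matches the instantiated model's count exactly.
    """
    c0 = cfg.channels[0]
    total = cfg.stem_kernel * in_channels * c0 + c0 + 2 * c0
    e = cfg.expansion
    dk = cfg.block_dw_kernel
    for d, c in zip(cfg.depths, cfg.channels):
        per_block = (dk * dk * 1 * c + c          # depthwise (2-D form) + bias
                     + 2 * c                      # layer norm affine
                     + c * e * c + e * c          # 1x1 expand
                     + e * c * c + c)             # 1x1 project
        total += d * per_block
    k = cfg.downsample_kernel
    for i in range(len(cfg.channels) - 1):
        if any(d > 0 for d in cfg.depths[i + 1:]):
            ci, cj = cfg.channels[i], cfg.channels[i + 1]
            total += 2 * ci + k * ci * cj + cj
    return int(total)


def depthwise_param_count(dk: int, m: int) -> int:
    """Dk * Dk * 1 * M — the depthwise layer's weight count."""
    return dk * dk * 1 * m


def standard_conv_param_count(dk: int, m: int, n: int) -> int:
    """Dk * Dk * M * N — a standard convolution's weight count."""
    return dk * dk * m * n
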