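"""Segmentation architectures: dense U-net (stage 1), residual attention
network (stage 2), and a plain U-Net baseline.

The stage-2 network is built from residual blocks with *spatial and channel
cascaded attention*. Inside a block the main path is a two-convolution
stack whose output first passes a spatial gate, then a channel gate:

* **spatial attention** — the C×H×W feature map is channel-wise max-pooled
  and mean-pooled into two 1×H×W maps, stacked, convolved (k×k, default 7),
  and squashed by a sigmoid into a per-position gate in (0,1) that
  multiplies every channel;
* **channel attention** — the (already spatially gated) map is globally
  max-pooled and mean-pooled over H×W into two C-vectors, each passed
  through a shared 1D convolution of adaptive kernel size ``K = log2(C)``
  (rounded half-up, floored at 1), summed and squashed into a per-channel
  gate that multiplies every position.

The block output is main-path plus shortcut; *identity* blocks use the raw
input as shortcut (and therefore require equal in/out widths), *convolution*
blocks use a 1×1 convolution. Encoders alternate convolution and identity
attention blocks with stride-2 downsampling; decoders alternate nearest-
neighbour upsampling with identity blocks; encoder and decoder levels are
joined by channel-concatenation skips, and a final 1×1 convolution emits
class logits.

The stage-1 network keeps the dense-connectivity mechanism — encoder stages
are dense blocks whose layer outputs are concatenated in series, linked by
compressing transition layers — inside the same U shape. Exact layer counts
are configuration with documented defaults, not fixed constants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ConfigError
from .nn.autograd import Tensor, concat, upsample2x_nearest
from .nn.layers import Module, Conv2d

__all__ = [
    "NetworkConfig", "attention_kernel_size", "SpatialAttention", "ChannelAttention",
    "AttentionResidualBlock", "build_residual_attention_net", "build_dense_unet",
    "build_baseline_unet", "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """One config type shared by the three builders; each uses the fields it
    needs. ``widths`` are encoder stage widths (decoder mirrors them)."""

    in_channels: int = 1
    n_classes: int = 2
    widths: tuple[int, ...] = (16, 32, 64)
    spatial_kernel: int = 7
    # dense U-net only
    growth_rate: int = 12
    dense_layers_per_block: int = 4
    dense_stages: int = 4
    compression: float = 0.5
    stem_width: int = 24
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.widths) or self.n_classes < 1 or self.in_channels < 1:
            raise ConfigError("widths, n_classes and in_channels must be positive")
        if self.spatial_kernel % 2 != 1:
            raise ConfigError("spatial_kernel must be odd")
        if not 0 < self.compression <= 1:
            raise ConfigError("compression must be in (0, 1]")


def attention_kernel_size(channels: int) -> int:
    """Adaptive channel-attention kernel ``K = log2(C)``, rounded half-up,
    never below 1."""
    if channels < 1:
        raise ConfigError(f"channel count must be >= 1, got {channels}")
    return max(1, math.floor(math.log2(channels) + 0.5))


class SpatialAttention(Module):
    """Per-position gate from stacked channel-wise max/mean pooling."""

    def __init__(self, kernel: int, rng):
        # edge padding: a spatially constant map keeps a constant gate
        self.conv = Conv2d(2, 1, kernel, rng, pad_mode="edge")

    def forward(self, f: Tensor) -> Tensor:
        pooled = concat([f.max(axis=1, keepdims=True), f.mean(axis=1, keepdims=True)], axis=1)
        gate = self.conv(pooled).sigmoid()  # (N,1,H,W)
        return f * gate


class ChannelAttention(Module):
    """Per-channel gate from global max/mean pooling through a shared
    adaptive-kernel 1D convolution (edge-replicate padding keeps the output
    length and makes identical channels gate identically; even K is padded
    asymmetrically)."""

    def __init__(self, channels: int, rng):
        self.kernel_size = attention_kernel_size(channels)
        self.conv = Conv2d(1, 1, (1, self.kernel_size), rng, pad_mode="edge")

    def forward(self, f: Tensor) -> Tensor:
        n, c = f.shape[:2]
        vmax = f.max(axis=3).max(axis=2).reshape(n, 1, 1, c)
        vmean = f.mean(axis=(2, 3)).reshape(n, 1, 1, c)
        gate = (self.conv(vmax) + self.conv(vmean)).sigmoid()  # (N,1,1,C)
        return f * gate.reshape(n, c, 1, 1)


class AttentionResidualBlock(Module):
    """Residual block with cascaded spatial-then-channel attention on the
    main path. ``mode`` is ``"convolution"`` (1×1-conv shortcut, width may
    change) or ``"identity"`` (raw shortcut, widths must match)."""

    attention_order = ("spatial", "channel")

    def __init__(self, in_ch: int, out_ch: int, rng, mode: str = "convolution",
                 spatial_kernel: int = 7):
        if mode not in ("convolution", "identity"):
            raise ConfigError(f"unknown block mode {mode!r}")
        if mode == "identity" and in_ch != out_ch:
            raise ConfigError(f"identity block needs equal widths, got {in_ch}->{out_ch}")
        self.mode = mode
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.spatial = SpatialAttention(spatial_kernel, rng)
        self.channel = ChannelAttention(out_ch, rng)
        self.shortcut = None if mode == "identity" else Conv2d(in_ch, out_ch, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).relu())
        h = self.channel(self.spatial(h))  # cascade: spatial first
        return h + (x if self.shortcut is None else self.shortcut(x))


class _Down(Module):
    def __init__(self, ch, rng):
        self.conv = Conv2d(ch, ch, 3, rng, stride=2, padding=(1, 1))

    def forward(self, x):
        return self.conv(x)


class _Up(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.conv = Conv2d(in_ch, out_ch, 3, rng)

    def forward(self, x):
        return self.conv(upsample2x_nearest(x)).relu()


class ResidualAttentionNet(Module):
    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        w = cfg.widths
        self.stem = Conv2d(cfg.in_channels, w[0], 3, rng)
        self.enc, self.downs = [], []
        prev = w[0]
        for i, width in enumerate(w):
            self.enc.append([
                AttentionResidualBlock(prev, width, rng, "convolution", cfg.spatial_kernel),
                AttentionResidualBlock(width, width, rng, "identity", cfg.spatial_kernel),
            ])
            if i < len(w) - 1:
                self.downs.append(_Down(width, rng))
            prev = width
        self.ups, self.merges, self.dec = [], [], []
        for i in range(len(w) - 2, -1, -1):
            self.ups.append(_Up(w[i + 1], w[i], rng))
            self.merges.append(Conv2d(2 * w[i], w[i], 1, rng))
            self.dec.append(AttentionResidualBlock(w[i], w[i], rng, "identity", cfg.spatial_kernel))
        self.head = Conv2d(w[0], cfg.n_classes, 1, rng)
        self.config = cfg

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            if name == "config":
                continue
            if isinstance(val, Module):
                out.extend(val.named_parameters(f"{prefix}{name}."))
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    items = item if isinstance(item, list) else [item]
                    for j, sub in enumerate(items):
                        out.extend(sub.named_parameters(f"{prefix}{name}.{i}.{j}."))
        return out

    def forward(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        skips = []
        for i, stage in enumerate(self.enc):
            for block in stage:
                h = block(h)
            skips.append(h)
            if i < len(self.downs):
                h = self.downs[i](h)
        for up, merge, block, skip in zip(self.ups, self.merges, self.dec, skips[-2::-1]):
            h = merge(concat([up(h), skip], axis=1))
            h = block(h)
        return self.head(h)


class _DenseBlock(Module):
    """``n_layers`` 3×3 conv layers of ``growth`` channels each, every layer
    consuming the concatenation of the block input and all earlier layer
    outputs. ``out_channels = in + n_layers * growth``."""

    def __init__(self, in_ch: int, n_layers: int, growth: int, rng):
        self.layers = [Conv2d(in_ch + i * growth, growth, 3, rng) for i in range(n_layers)]
        self.out_channels = in_ch + n_layers * growth

    def forward(self, x: Tensor) -> Tensor:
        feats = [x]
        for layer in self.layers:
            h = layer(feats[0] if len(feats) == 1 else concat(feats, axis=1)).relu()
            feats.append(h)
        return concat(feats, axis=1)


class DenseUNet(Module):
    """U-shaped network with dense-block encoder stages.

    A stride-2 stem (as in DenseNet) moves the dense blocks to half
    resolution; a light full-resolution side feature provides the topmost
    skip so logits come back at input size."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        side_ch = max(4, cfg.stem_width // 3)
        self.side = Conv2d(cfg.in_channels, side_ch, 3, rng)
        self.stem = Conv2d(cfg.in_channels, cfg.stem_width, 3, rng, stride=2, padding=(1, 1))
        self.blocks, self.transitions = [], []
        skip_chs = []
        ch = cfg.stem_width
        for s in range(cfg.dense_stages):
            block = _DenseBlock(ch, cfg.dense_layers_per_block, cfg.growth_rate, rng)
            self.blocks.append(block)
            skip_chs.append(block.out_channels)
            ch = block.out_channels
            if s < cfg.dense_stages - 1:
                comp = max(1, int(ch * cfg.compression))
                self.transitions.append(Conv2d(ch, comp, 2, rng, stride=2, padding=(0, 0)))
                ch = comp
        self.ups, self.decs = [], []
        for i in range(cfg.dense_stages - 2, -1, -1):
            self.ups.append(_Up(ch, skip_chs[i], rng))
            self.decs.append(Conv2d(2 * skip_chs[i], skip_chs[i], 3, rng))
            ch = skip_chs[i]
        self.final_up = _Up(ch, cfg.stem_width, rng)
        self.head = Conv2d(cfg.stem_width + side_ch, cfg.n_classes, 1, rng)
        self.config = cfg

    def forward(self, x: Tensor) -> Tensor:
        side = self.side(x).relu()
        h = self.stem(x)
        skips = []
        for i, block in enumerate(self.blocks):
            h = block(h)
            skips.append(h)
            if i < len(self.transitions):
                h = self.transitions[i](h).relu()
        for up, dec, skip in zip(self.ups, self.decs, skips[-2::-1]):
            h = dec(concat([up(h), skip], axis=1)).relu()
        h = self.final_up(h)
        return self.head(concat([h, side], axis=1))

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            if name in ("config",):
                continue
            if isinstance(val, Module):
                out.extend(val.named_parameters(f"{prefix}{name}."))
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out


class _DoubleConv(Module):
    def __init__(self, in_ch, out_ch, rng):
        self.c1 = Conv2d(in_ch, out_ch, 3, rng)
        self.c2 = Conv2d(out_ch, out_ch, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).relu()).relu()


class BaselineUNet(Module):
    """Symmetric encoder–decoder with concatenation skips."""

    def __init__(self, cfg: NetworkConfig):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
        w = cfg.widths
        self.enc, self.downs = [], []
        prev = cfg.in_channels
        for i, width in enumerate(w):
            self.enc.append(_DoubleConv(prev, width, rng))
            if i < len(w) - 1:
                self.downs.append(_Down(width, rng))
            prev = width
        self.ups, self.decs = [], []
        for i in range(len(w) - 2, -1, -1):
            self.ups.append(_Up(w[i + 1], w[i], rng))
            self.decs.append(_DoubleConv(2 * w[i], w[i], rng))
        self.head = Conv2d(w[0], cfg.n_classes, 1, rng)
        self.config = cfg

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, val in vars(self).items():
            if name == "config":
                continue
            if isinstance(val, Module):
                out.extend(val.named_parameters(f"{prefix}{name}."))
            elif isinstance(val, list):
                for i, item in enumerate(val):
                    out.extend(item.named_parameters(f"{prefix}{name}.{i}."))
        return out

    def forward(self, x: Tensor) -> Tensor:
        h = Tensor(x.data) if not isinstance(x, Tensor) else x
        skips = []
        for i, stage in enumerate(self.enc):
            h = stage(h)
            skips.append(h)
            if i < len(self.downs):
                h = self.downs[i](h)
        for up, dec, skip in zip(self.ups, self.decs, skips[-2::-1]):
            h = dec(concat([up(h), skip], axis=1))
        return self.head(h)


def build_residual_attention_net(cfg: NetworkConfig) -> ResidualAttentionNet:
    return ResidualAttentionNet(cfg)


def build_dense_unet(cfg: NetworkConfig) -> DenseUNet:
    return DenseUNet(cfg)


def build_baseline_unet(cfg: NetworkConfig) -> BaselineUNet:
    return BaselineUNet(cfg)


_ARCHS = {
    "residual_attention": build_residual_attention_net,
    "dense_unet": build_dense_unet,
    "baseline_unet": build_baseline_unet,
}


def save_checkpoint(path, model: Module, arch: str) -> None:
    """Serialise weights + full config + seed into one ``.npz`` file."""
    if arch not in _ARCHS:
        raise ConfigError(f"unknown architecture {arch!r}")
    meta = json.dumps({"arch": arch, "config": asdict(model.config)})
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> Module:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    cfg_dict = meta["config"]
    cfg_dict["widths"] = tuple(cfg_dict["widths"])
    model = _ARCHS[meta["arch"]](NetworkConfig(**cfg_dict))
    model.load_state_dict(state)
    return model
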