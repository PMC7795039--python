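"""Residual convolutional backbone with per-stage channel attention.

The backbone is a five-stage strided CNN in the ResNet family: a stem stage
followed by four stages of basic residual blocks, each stage halving every
spatial extent.  After every stage the feature map is re-weighted channel by
channel by a learned attention module, and the final stage is collapsed by
global average pooling into the shared feature vector consumed by the task
heads.

The attention module computes, per sample, a vector of channel attention
factors (CAF) in (0, 1): the stage output is globally max-pooled to one cell
per channel, flattened, passed through a 1x1 convolution that reduces the
channel count by a factor ``r``, batch-normalized, ReLU-activated, restored
to the full channel count by a fully connected layer, and squashed by a
sigmoid.  The factors multiply the feature map channel-wise, so attention is
a per-channel contraction (|output| <= |input| entrywise) and, because the
pooling is global, the factors are invariant to any spatial shuffling of the
stage output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BackboneConfig",
    "FeatureMap",
    "AttentionModule",
    "ResidualBlock",
    "Backbone",
    "channel_attention",
    "apply_attention",
    "backbone_forward",
]

N_STAGES = 5


@dataclass
class BackboneConfig:
    """Architecture of the shared feature extractor.

    ``input_size`` must be divisible by the total downsampling factor
    2**5 = 32 (five stride-2 stages), and ``attention_reduction`` must divide
    every entry of ``stage_channels``.
    """

    dimensionality: int = 2
    stage_channels: tuple[int, ...] = (32, 64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (1, 2, 2, 2, 2)
    attention_reduction: int = 4
    input_channels: int = 1
    input_size: tuple[int, ...] = (128, 128)
    use_attention: bool = True

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.blocks_per_stage = tuple(int(b) for b in self.blocks_per_stage)
        self.input_size = tuple(int(s) for s in self.input_size)
        if len(self.stage_channels) != N_STAGES or len(self.blocks_per_stage) != N_STAGES:
            raise ValueError("exactly five stages are required")
        if min(self.stage_channels) < 1 or min(self.blocks_per_stage) < 1:
            raise ValueError("stage widths and block counts must be positive")
        if len(self.input_size) != self.dimensionality:
            raise ValueError("input_size rank must match dimensionality")
        total_down = 2**N_STAGES
        if any(s % total_down for s in self.input_size):
            raise ValueError(f"input_size must be divisible by {total_down}")
        r = self.attention_reduction
        if r < 1 or any(c % r for c in self.stage_channels):
            raise ValueError("attention_reduction must divide every stage width")

    @property
    def feature_dim(self) -> int:
        return self.stage_channels[-1]

    @classmethod
    def default_3d(cls, input_size: tuple[int, int, int] = (32, 32, 32)) -> "BackboneConfig":
        """Narrower widths suited to volumetric inputs."""
        return cls(
            dimensionality=3,
            stage_channels=(16, 32, 64, 64, 128),
            blocks_per_stage=(1, 2, 2, 2, 2),
            input_size=input_size,
        )


@dataclass
class FeatureMap:
    """A batch of multi-channel spatial activations at one backbone stage."""

    values: np.ndarray
    stage_index: int = 1
    scale: int = 1

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim < 3:
            raise ValueError("feature map needs (batch, channels, spatial...) axes")
        if v.shape[1] < 1 or min(v.shape[2:]) < 1:
            raise ValueError("channel and spatial extents must be >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map contains non-finite values")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def _fmap_tensor(fmap) -> Tensor:
    if isinstance(fmap, FeatureMap):
        return Tensor(fmap.values)
    if isinstance(fmap, Tensor):
        return fmap
    return Tensor(np.asarray(fmap, dtype=float))


class AttentionModule(nn.Module):
    """Channel attention: global max-pool -> 1x1 conv -> BN -> ReLU -> FC -> sigmoid."""

    def __init__(self, n_channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        if n_channels % reduction:
            raise ValueError("reduction must divide the channel count")
        hidden = n_channels // reduction
        self.n_channels = n_channels
        # acting on a flattened 1x1xC vector, the 1x1 convolution is a dense map
        self.reduce = nn.Linear(n_channels, hidden, rng)
        self.bn = nn.BatchNorm(hidden, feature_axis=-1)
        self.expand = nn.Linear(hidden, n_channels, rng)

    def forward(self, fmap: Tensor) -> Tensor:
        if fmap.data.shape[1] != self.n_channels:
            raise ValueError(
                f"attention module sized for {self.n_channels} channels, "
                f"got {fmap.data.shape[1]}"
            )
        spatial_axes = tuple(range(2, fmap.data.ndim))
        pooled = nn.reduce_max(fmap, axis=spatial_axes)  # (B, C)
        h = nn.relu(self.bn(self.reduce(pooled)))
        return nn.sigmoid(self.expand(h))  # CAF in (0, 1)


def channel_attention(fmap, am: AttentionModule) -> Tensor:
    """Compute the channel attention factors for ``fmap`` (shape (B, C))."""
    return am(_fmap_tensor(fmap))


def apply_attention(fmap, caf) -> Tensor:
    """Re-weight each channel of ``fmap`` by its attention factor.

    ``caf`` has shape (B, C) (or (C,), broadcast over the batch); the result
    has exactly the shape of ``fmap``.
    """
    t = _fmap_tensor(fmap)
    c = caf if isinstance(caf, Tensor) else Tensor(np.asarray(caf, dtype=float))
    n_ch = t.data.shape[1]
    if c.data.shape[-1] != n_ch:
        raise ValueError(
            f"attention factor length {c.data.shape[-1]} != channel count {n_ch}"
        )
    shape = c.data.shape[:-1] + (n_ch,) + (1,) * (t.data.ndim - 2)
    return nn.mul(t, nn.reshape(c, shape))


class ResidualBlock(nn.Module):
    """Basic two-convolution residual block with a projection shortcut."""

    def __init__(self, dim: int, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv(dim, c_in, c_out, 3, stride, 1, rng)
        self.bn1 = nn.BatchNorm(c_out)
        self.conv2 = nn.Conv(dim, c_out, c_out, 3, 1, 1, rng)
        self.bn2 = nn.BatchNorm(c_out)
        self.project = None
        if stride != 1 or c_in != c_out:
            self.project = nn.Sequential(
                nn.Conv(dim, c_in, c_out, 1, stride, 0, rng),
                nn.BatchNorm(c_out),
            )

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        skip = x if self.project is None else self.project(x)
        return nn.relu(h + skip)


class Backbone(nn.Module):
    """Five downsampling stages, each followed by channel attention."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        dim = cfg.dimensionality
        ch = cfg.stage_channels
        # stage 1 is a convolutional stem; stages 2-5 are residual
        self.stem = nn.Sequential(
            nn.Conv(dim, cfg.input_channels, ch[0], 3, 2, 1, rng),
            nn.BatchNorm(ch[0]),
            nn.ReLU(),
        )
        self.stages: list[nn.Module] = []
        c_prev = ch[0]
        for i in range(1, N_STAGES):
            blocks = [ResidualBlock(dim, c_prev, ch[i], 2, rng)]
            for _ in range(cfg.blocks_per_stage[i] - 1):
                blocks.append(ResidualBlock(dim, ch[i], ch[i], 1, rng))
            self.stages.append(nn.Sequential(*blocks))
            c_prev = ch[i]
        self.attention: list[AttentionModule] = []
        if cfg.use_attention:
            self.attention = [
                AttentionModule(ch[i], cfg.attention_reduction, rng)
                for i in range(N_STAGES)
            ]

    def _check_input(self, x: Tensor) -> None:
        expected = (self.cfg.input_channels,) + self.cfg.input_size
        if x.data.ndim != len(expected) + 1 or x.data.shape[1:] != expected:
            raise ValueError(
                f"expected input of shape (batch, {expected}), got {x.data.shape}"
            )
        if not np.all(np.isfinite(x.data)):
            raise ValueError("input contains non-finite values")

    def forward(self, x: Tensor) -> Tensor:
        """Map an image batch to the shared feature vector Vf (B, C5)."""
        self._check_input(x)
        h = self.stem(x)
        if self.attention:
            h = apply_attention(h, self.attention[0](h))
        for i, stage in enumerate(self.stages):
            h = stage(h)
            if self.attention:
                h = apply_attention(h, self.attention[i + 1](h))
        spatial_axes = tuple(range(2, h.data.ndim))
        return nn.reduce_mean(h, axis=spatial_axes)  # GAP -> (B, C5)


def backbone_forward(image, backbone: Backbone, mode: str = "eval") -> Tensor:
    """Run the backbone on an image batch in ``"train"`` or ``"eval"`` mode."""
    if mode not in ("train", "eval"):
        raise ValueError("mode must be 'train' or 'eval'")
    (backbone.train() if mode == "train" else backbone.eval())
    x = image if isinstance(image, Tensor) else Tensor(np.asarray(image, dtype=float))
    return backbone(x)
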