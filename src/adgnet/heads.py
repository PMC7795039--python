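"""The two task heads sharing the backbone's feature vector.

Classification sub-network (CSN): a single fully connected layer mapping the
shared feature vector Vf to one logit per class, squashed entrywise by a
sigmoid into the prediction vector Vp.  The per-class probabilities are
independent sigmoids, not a softmax (a softmax variant is available behind a
flag); the predicted label is the argmax of Vp with ties broken toward the
lowest index.

Reconstruction sub-network (RSN): two fully connected layers (ReLU between
them) encode Vf into a vector Ve that reshapes to a small seed feature map;
a stack of M stride-2 kernel-3 transposed convolutions with ReLU doubles
every spatial extent M times; a final kernel-3 convolution restores the
image channel count and a tanh bounds the reconstruction to (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "DecoderConfig",
    "classify",
    "predict_label",
    "ClassificationHead",
    "Encoder",
    "Decoder",
]


@dataclass
class DecoderConfig:
    """Geometry of the reconstruction decoder.

    The seed map is (base_channels, base_size, ...); after M exact-doubling
    transposed convolutions the spatial extent is base_size * 2**M, which
    must equal the input image's extent on every axis.
    """

    M: int = 5
    base_size: int = 4
    base_channels: int = 8
    out_channels: int = 1
    dimensionality: int = 2

    def __post_init__(self):
        if self.M < 1 or self.base_size < 1 or self.base_channels < 1:
            raise ValueError("decoder geometry fields must be positive")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")

    @property
    def output_extent(self) -> int:
        return self.base_size * 2**self.M

    @property
    def encoded_dim(self) -> int:
        """Length of Ve: base_size**dim * base_channels."""
        return self.base_size**self.dimensionality * self.base_channels

    def validate_against(self, input_size: tuple[int, ...]) -> None:
        if any(s != self.output_extent for s in input_size):
            raise ValueError(
                f"decoder produces extent {self.output_extent} "
                f"(base {self.base_size} x 2^{self.M}) but the input image is "
                f"{input_size}"
            )


class ClassificationHead(nn.Module):
    """One affine map followed by an element-wise sigmoid (or softmax)."""

    def __init__(self, feature_dim: int, n_classes: int, rng: np.random.Generator,
                 use_softmax: bool = False):
        super().__init__()
        self.fcp = nn.Linear(feature_dim, n_classes, rng)
        self.use_softmax = use_softmax

    def forward(self, vf: Tensor) -> Tensor:
        logits = self.fcp(vf)
        if self.use_softmax:
            shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
            ez = _exp(shifted)
            return ez * nn.power(nn.reduce_sum(ez, axis=-1, keepdims=True), -1.0)
        return nn.sigmoid(logits)


def _exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def backward(g):
        x._accum(g * out_data)

    out = Tensor(out_data)
    if x.requires_grad or x._parents:
        out._parents = (x,)
        out._backward = backward
    return out


def classify(vf, head: ClassificationHead) -> Tensor:
    """Prediction vector Vp = sigma(FC(Vf)); entries strictly in (0, 1)."""
    t = vf if isinstance(vf, Tensor) else Tensor(np.asarray(vf, dtype=float))
    if not np.all(np.isfinite(t.data)):
        raise ValueError("feature vector contains non-finite values")
    return head(t)


def predict_label(vp) -> np.ndarray:
    """Index of the largest class probability; ties go to the lowest index."""
    v = vp.data if isinstance(vp, Tensor) else np.asarray(vp, dtype=float)
    if v.size == 0 or v.shape[-1] == 0:
        raise ValueError("empty prediction vector")
    return np.argmax(v, axis=-1)


class Encoder(nn.Module):
    """Vf -> Ve through FCe1, ReLU, FCe2."""

    def __init__(self, feature_dim: int, encoded_dim: int,
                 rng: np.random.Generator, hidden: int | None = None):
        super().__init__()
        hidden = encoded_dim if hidden is None else hidden
        self.fce1 = nn.Linear(feature_dim, hidden, rng)
        self.fce2 = nn.Linear(hidden, encoded_dim, rng)

    def forward(self, vf: Tensor) -> Tensor:
        return self.fce2(nn.relu(self.fce1(vf)))


class Decoder(nn.Module):
    """Seed map -> M exact-doubling transposed convolutions -> conv -> tanh."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        dim = cfg.dimensionality
        # channel schedule: halve per upsampling step, floored at 4
        chans = [cfg.base_channels]
        for m in range(cfg.M):
            chans.append(max(cfg.base_channels // 2 ** (m + 1), 4))
        self.upsample: list[nn.Module] = [
            nn.ConvTranspose(dim, chans[m], chans[m + 1], rng) for m in range(cfg.M)
        ]
        # "dimension normalization": kernel-3 stride-1 conv to the image channels
        self.final = nn.Conv(dim, chans[-1], cfg.out_channels, 3, 1, 1, rng)

    def forward(self, ve: Tensor) -> Tensor:
        cfg = self.cfg
        if ve.data.shape[-1] != cfg.encoded_dim:
            raise ValueError(
                f"encoded vector length {ve.data.shape[-1]} != "
                f"{cfg.encoded_dim} required by the decoder seed map"
            )
        seed_shape = (-1, cfg.base_channels) + (cfg.base_size,) * cfg.dimensionality
        h = nn.reshape(ve, seed_shape)
        for layer in self.upsample:
            h = nn.relu(layer(h))
        return nn.tanh(self.final(h))
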