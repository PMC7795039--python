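"""Training objectives: weighted classification loss, reconstruction MSE,
and their linear combination.

The classification loss is a class-weighted modification of binary
cross-entropy applied independently to every (sample, class) sigmoid output:

    Lcls = -(1/N) * sum[ (1-i)^gamma * log(1-i') + i^gamma * log(i') ]

where ``i`` is the target probability, ``i'`` the prediction (clamped to
[eps, 1-eps]), ``gamma`` a per-class weight-reduction exponent (default 2),
and N the number of (sample, class) terms.  For hard labels i in {0, 1} the
exponents are inert (0^g = 0, 1^g = 1) and the loss is exactly binary
cross-entropy.  A conventional focal variant — modulating the *predicted*
probability, (1-i')^gamma on the positive term and i'^gamma on the negative
term — is available via ``FocalParams.variant = "focal"``.

The reconstruction loss is the mean squared error per pixel/voxel, and the
total objective is L = lambda1 * Lcls + lambda2 * Lrec.  A term whose lambda
is zero is omitted from the computation graph entirely, so its parameters
receive exactly zero gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "LossWeights",
    "FocalParams",
    "classification_loss",
    "reconstruction_loss",
    "combined_loss",
]


@dataclass
class LossWeights:
    """Balance between the classification and reconstruction terms."""

    lambda1: float = 1.0
    lambda2: float = 1.0

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda1 == 0 and self.lambda2 == 0:
            raise ValueError("at least one loss weight must be positive")


@dataclass
class FocalParams:
    """Class-wise weight-reduction exponents and the probability clamp."""

    gamma: float | tuple[float, ...] = 2.0
    epsilon: float = 1e-7
    variant: str = "literal"  # "literal" (exponent on targets) or "focal"

    def __post_init__(self):
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any(g < 0):
            raise ValueError("gamma must be nonnegative")
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.variant not in ("literal", "focal"):
            raise ValueError("variant must be 'literal' or 'focal'")

    def gamma_vector(self, n_classes: int) -> np.ndarray:
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if g.size == 1:
            return np.full(n_classes, float(g[0]))
        if g.size != n_classes:
            raise ValueError(f"gamma has {g.size} entries for {n_classes} classes")
        return g


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def classification_loss(truth, pred, fp: FocalParams | None = None) -> Tensor:
    """Mean weighted cross-entropy over all (sample, class) terms."""
    fp = fp or FocalParams()
    t = np.atleast_2d(np.asarray(truth, dtype=float))
    p = _as_tensor(pred)
    pdata = np.atleast_2d(p.data)
    if t.shape != pdata.shape:
        raise ValueError(f"truth shape {t.shape} != prediction shape {pdata.shape}")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("target probabilities must lie in [0, 1]")
    if p.data.ndim == 1:
        p = nn.reshape(p, (1, -1))
    gamma = fp.gamma_vector(t.shape[-1])
    pc = nn.clip(p, fp.epsilon, 1.0 - fp.epsilon)
    log_p = nn.log(pc)
    log_1p = nn.log(1.0 - pc)
    if fp.variant == "literal":
        pos_w = Tensor(t**gamma)
        neg_w = Tensor((1.0 - t) ** gamma)
        terms = neg_w * log_1p + pos_w * log_p
    else:
        # focal: i * (1-i')^gamma * log(i') + (1-i) * i'^gamma * log(1-i')
        terms = Tensor(t) * _pow_t(1.0 - pc, gamma) * log_p + Tensor(1.0 - t) * _pow_t(
            pc, gamma
        ) * log_1p
    return -1.0 * nn.reduce_mean(terms)


def _pow_t(base: Tensor, gamma: np.ndarray) -> Tensor:
    """base ** gamma with a (constant) per-class exponent vector."""
    g = np.broadcast_to(gamma, base.data.shape)
    out_data = base.data**g

    def backward(grad):
        base._accum(grad * g * base.data ** (g - 1.0))

    out = Tensor(out_data)
    if base.requires_grad or base._parents:
        out._parents = (base,)
        out._backward = backward
    return out


def reconstruction_loss(y, yhat) -> Tensor:
    """Mean squared error per pixel/voxel between image and reconstruction."""
    yh = _as_tensor(yhat)
    yt = np.asarray(y, dtype=float)
    if yt.shape != yh.data.shape:
        raise ValueError(f"image shape {yt.shape} != reconstruction shape {yh.data.shape}")
    diff = yh - Tensor(yt)
    return nn.reduce_mean(diff * diff)


def combined_loss(lcls, lrec, weights: LossWeights) -> Tensor:
    """L = lambda1 * Lcls + lambda2 * Lrec; zero-lambda terms leave the graph."""
    terms = []
    if weights.lambda1 != 0.0:
        if lcls is None:
            raise ValueError("lambda1 > 0 but no classification loss given")
        _check_finite(lcls)
        terms.append(weights.lambda1 * _as_tensor(lcls))
    if weights.lambda2 != 0.0:
        if lrec is None:
            raise ValueError("lambda2 > 0 but no reconstruction loss given")
        _check_finite(lrec)
        terms.append(weights.lambda2 * _as_tensor(lrec))
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total


def _check_finite(x) -> None:
    data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("loss term is non-finite")
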