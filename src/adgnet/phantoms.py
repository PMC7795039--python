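"""Synthetic class-graded brain phantoms.

Each phantom is a noisy 2D image or 3D volume containing an elliptical
"brain" of elevated intensity on a dark background, with a central
low-intensity "ventricle" whose area (2D) or volume (3D) grows with the
class index:

    region size  ~  base size * (1 + class_index * severity_effect)

so classes differ by a graded morphological change — mirroring ventricular
enlargement / atrophy as the discriminative cue in dementia imaging — rather
than by raw intensity.  Position and eccentricity are jittered per instance
(area-preserving), Gaussian noise is added, and the image is clamped to
[-1, 1], the tanh range of the reconstruction head, so no normalization
round-trip is needed.

With ``severity_effect = 0`` every class has the same image distribution and
labels carry no signal; that null configuration anchors the sanity floor for
the ablation benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trainer import LabeledDataset

__all__ = ["PhantomSpec", "Phantom", "generate_phantom", "generate_dataset", "PhantomSplit"]

CLASS_NAME_POOL = [
    "grade0_none",
    "grade1_very_mild",
    "grade2_mild",
    "grade3_moderate",
]


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    ``size`` is the spatial extent on every axis (power of two so it is
    compatible with the exact-doubling decoder); ``counts_per_class`` sets
    the dataset composition; ``severity_effect`` is the relative enlargement
    of the inner region per class step.
    """

    dimensionality: int = 2
    size: int = 128
    n_classes: int = 4
    severity_effect: float = 0.6
    noise_sd: float = 0.2
    counts_per_class: tuple[int, ...] = (125, 125, 125, 125)
    seed: int = 0

    def __post_init__(self):
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.size < 8 or (self.size & (self.size - 1)) != 0:
            raise ValueError("size must be a power of two >= 8")
        if not 2 <= self.n_classes <= 4:
            raise ValueError("n_classes must be between 2 and 4")
        if self.severity_effect < 0 or self.noise_sd < 0:
            raise ValueError("severity_effect and noise_sd must be >= 0")
        self.counts_per_class = tuple(int(c) for c in self.counts_per_class)
        if len(self.counts_per_class) != self.n_classes:
            raise ValueError("counts_per_class length must equal n_classes")
        if min(self.counts_per_class) < 1:
            raise ValueError("every class needs at least one phantom")

    @property
    def class_names(self) -> list[str]:
        return CLASS_NAME_POOL[: self.n_classes]

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.size,) * self.dimensionality


@dataclass
class Phantom:
    image: np.ndarray
    label: int
    metadata: dict = field(default_factory=dict)


# intensities (already in the tanh range)
_BACKGROUND = -0.8
_TISSUE = 0.5
_VENTRICLE = -0.5
_BRAIN_SEMI_AXES = (0.80, 0.65, 0.72)  # fractions of the half-extent
_INNER_BASE_RADIUS = 0.20  # fraction of the half-extent


def generate_phantom(spec: PhantomSpec, class_index: int, instance_seed: int) -> Phantom:
    """One deterministic phantom of the given class.

    The inner-region linear scale is the (1 + class_index * severity_effect)
    factor taken to the 1/dim power, so its area (2D) or volume (3D) scales
    linearly with the factor.  Jitter of the eccentricity preserves that
    area/volume; jitter of the center moves the region without resizing it.
    """
    if not 0 <= class_index < spec.n_classes:
        raise ValueError(f"class_index {class_index} outside [0, {spec.n_classes})")
    dim = spec.dimensionality
    rng = np.random.default_rng([spec.seed, class_index, instance_seed])
    axes = [np.linspace(-1.0, 1.0, spec.size) for _ in range(dim)]
    grids = np.meshgrid(*axes, indexing="ij")

    brain_axes = np.array(_BRAIN_SEMI_AXES[:dim]) * rng.uniform(0.95, 1.05, size=dim)
    brain = sum((g / a) ** 2 for g, a in zip(grids, brain_axes)) <= 1.0

    factor = 1.0 + class_index * spec.severity_effect
    radius = _INNER_BASE_RADIUS * factor ** (1.0 / dim)
    ecc = rng.uniform(0.9, 1.1, size=dim)
    ecc /= np.prod(ecc) ** (1.0 / dim)  # normalize so the volume is preserved
    center = rng.uniform(-0.08, 0.08, size=dim)
    inner = sum(
        ((g - c) / (radius * e)) ** 2 for g, c, e in zip(grids, center, ecc)
    ) <= 1.0
    inner &= brain

    image = np.full(spec.shape, _BACKGROUND)
    image[brain] = _TISSUE
    image[inner] = _VENTRICLE
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    image = np.clip(image, -1.0, 1.0)
    return Phantom(
        image=image,
        label=class_index,
        metadata={
            "class_index": class_index,
            "instance_seed": int(instance_seed),
            "severity_factor": factor,
            "inner_cells": int(inner.sum()),
            "brain_cells": int(brain.sum()),
        },
    )


@dataclass
class PhantomSplit:
    """A phantom dataset with its deterministic train-val / test partition."""

    data: LabeledDataset
    tvs_indices: np.ndarray
    ts_indices: np.ndarray

    @property
    def tvs(self) -> LabeledDataset:
        return self.data.subset(self.tvs_indices)

    @property
    def ts(self) -> LabeledDataset:
        return self.data.subset(self.ts_indices)


def generate_dataset(spec: PhantomSpec, test_fraction: float = 0.2) -> PhantomSplit:
    """Generate ``counts_per_class`` phantoms per class with an 80/20
    stratified train-val / test split (deterministic from ``spec.seed``)."""
    images, labels = [], []
    for c, count in enumerate(spec.counts_per_class):
        for j in range(count):
            ph = generate_phantom(spec, c, j)
            images.append(ph.image)
            labels.append(c)
    images = np.stack(images)
    labels = np.asarray(labels)
    ds = LabeledDataset(images, labels, spec.class_names)

    rng = np.random.default_rng([spec.seed, 10**6])
    ts = []
    for c, count in enumerate(spec.counts_per_class):
        members = np.flatnonzero(labels == c)
        n_test = max(1, int(np.floor(test_fraction * count + 0.5)))
        ts.append(rng.choice(members, size=n_test, replace=False))
    ts_idx = np.sort(np.concatenate(ts))
    tvs_idx = np.setdiff1d(np.arange(len(labels)), ts_idx)
    return PhantomSplit(data=ds, tvs_indices=tvs_idx, ts_indices=ts_idx)
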