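"""Semi-supervised training protocol.

Labels are scarce by construction: a stratified subset (default 20%) of the
training-validation set keeps its labels, the rest are masked.  Every
optimization step minimizes

    lambda1 * Lcls(labeled items in the batch) + lambda2 * Lrec(all items)

so unlabeled images contribute only through the reconstruction term — the
mechanism by which the reconstruction head turns unlabeled data into shared
features.  Model selection keeps the parameters of the epoch with the best
validation macro-F1, computed over the labeled validation items.

Cross-validation folds are stratified on the ground-truth class labels
(scikit-learn's StratifiedKFold), and one integer seed drives label
subsetting, fold assignment, weight initialization and batch order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .backbone import BackboneConfig
from .heads import DecoderConfig, predict_label
from .losses import FocalParams, LossWeights, classification_loss, combined_loss, reconstruction_loss
from .metrics import macro_average, one_vs_rest_metrics
from .model import MultiTaskNet
from . import nn
from .nn import Tensor

__all__ = [
    "LabeledDataset",
    "TrainConfig",
    "stratified_label_subset",
    "make_folds",
    "train",
    "evaluate_on_test",
    "write_history",
]


@dataclass
class LabeledDataset:
    """Images with (possibly masked) class labels.

    ``labels`` holds the ground-truth class index of every item;
    ``labeled_mask`` says which labels are visible to training.  Stratified
    operations always use the ground-truth labels.
    """

    images: np.ndarray  # (N, *spatial)
    labels: np.ndarray  # (N,) int
    class_names: list[str]
    labeled_mask: np.ndarray | None = None  # (N,) bool; default all True

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labeled_mask is None:
            self.labeled_mask = np.ones(len(self.labels), dtype=bool)
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        if len(self.images) != len(self.labels) or len(self.labels) != len(self.labeled_mask):
            raise ValueError("images, labels and labeled_mask lengths differ")
        n_classes = len(self.class_names)
        lab = self.labels[self.labeled_mask]
        if lab.size and (lab.min() < 0 or lab.max() >= n_classes):
            raise ValueError("labeled item with class index outside [0, n_classes)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.images[idx], self.labels[idx], list(self.class_names),
            self.labeled_mask[idx],
        )

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)


@dataclass
class TrainConfig:
    """Everything the training loop needs besides the architecture."""

    label_fraction: float = 0.2
    folds: int = 5
    seed: int = 0
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss_weights: LossWeights = field(default_factory=LossWeights)
    focal: FocalParams = field(default_factory=FocalParams)
    use_rsn: bool = True
    use_am: bool = True
    use_unlabeled: bool = True
    use_softmax: bool = False

    def __post_init__(self):
        if not 0 < self.label_fraction <= 1:
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is available")


def stratified_label_subset(ds: LabeledDataset, fraction: float, seed: int) -> LabeledDataset:
    """Keep round(fraction * n_c) labels per class (at least 1), mask the rest.

    Image data and ground-truth labels are untouched; only the visibility
    mask changes.  Deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    counts = ds.class_counts()
    if np.any(counts == 0):
        empty = [ds.class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"classes with no members: {empty}")
    rng = np.random.default_rng(seed)
    mask = np.zeros(len(ds), dtype=bool)
    for c in range(ds.n_classes):
        members = np.flatnonzero(ds.labels == c)
        n_keep = max(1, int(np.floor(fraction * members.size + 0.5)))
        keep = rng.choice(members, size=n_keep, replace=False)
        mask[keep] = True
    return LabeledDataset(ds.images, ds.labels, list(ds.class_names), mask)


def make_folds(ds: LabeledDataset, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition: list of (train_indices, val_indices)."""
    counts = ds.class_counts()
    if np.any(counts < k):
        raise ValueError(f"every class needs >= {k} members, got counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**32)
    return [
        (np.asarray(tr, dtype=int), np.asarray(va, dtype=int))
        for tr, va in skf.split(np.zeros(len(ds)), ds.labels)
    ]


def _val_macro_f1(model: MultiTaskNet, ds: LabeledDataset, indices: np.ndarray) -> float:
    labeled = indices[ds.labeled_mask[indices]]
    if labeled.size == 0:
        return float("nan")
    probs = model.predict_proba(ds.images[labeled])
    y_pred = predict_label(probs)
    y_true = ds.labels[labeled]
    ms = macro_average(one_vs_rest_metrics(y_true, y_pred, range(ds.n_classes)))
    return ms.f1


def train(
    ds: LabeledDataset,
    cfg: TrainConfig,
    backbone_cfg: BackboneConfig,
    decoder_cfg: DecoderConfig | None = None,
    train_indices=None,
    val_indices=None,
) -> tuple[MultiTaskNet, list[dict]]:
    """Train the multi-task network; returns (model, per-epoch history).

    If no train/validation split is given, the first stratified fold of
    ``cfg.folds`` is held out for validation.  Ablation switches in ``cfg``
    control whether the reconstruction head and the attention modules exist
    at all.
    """
    if len(ds) == 0:
        raise ValueError("empty dataset")
    w = cfg.loss_weights
    rng = np.random.default_rng(cfg.seed)
    init_seed = int(rng.integers(2**31))
    fold_seed = int(rng.integers(2**31))

    if train_indices is None or val_indices is None:
        train_indices, val_indices = make_folds(ds, cfg.folds, fold_seed)[0]
    train_indices = np.asarray(train_indices, dtype=int)
    val_indices = np.asarray(val_indices, dtype=int)

    if not cfg.use_unlabeled:
        train_indices = train_indices[ds.labeled_mask[train_indices]]
    n_labeled = int(ds.labeled_mask[train_indices].sum())
    if w.lambda1 > 0 and n_labeled == 0:
        raise ValueError("lambda1 > 0 requires at least one labeled training item")

    bb_cfg = replace(backbone_cfg, use_attention=cfg.use_am)
    dec_cfg = decoder_cfg if cfg.use_rsn else None
    model = MultiTaskNet(
        bb_cfg, ds.n_classes, dec_cfg, seed=init_seed, use_softmax=cfg.use_softmax
    )
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    eye = np.eye(ds.n_classes)
    use_recon = model.has_rsn and w.lambda2 > 0

    history: list[dict] = []
    best_f1 = -np.inf
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(train_indices)
        lcls_sum = lrec_sum = 0.0
        lcls_steps = lrec_steps = 0
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            x = ds.images[idx][:, None]  # channel axis
            xt = Tensor(x)
            vp, imr = model.forward(xt, with_reconstruction=use_recon)
            lcls = lrec = None
            labeled_rows = np.flatnonzero(ds.labeled_mask[idx])
            if w.lambda1 > 0 and labeled_rows.size:
                truth = eye[ds.labels[idx[labeled_rows]]]
                lcls = classification_loss(
                    truth, nn.take_rows(vp, labeled_rows), cfg.focal
                )
                lcls_sum += lcls.item()
                lcls_steps += 1
            if use_recon:
                lrec = reconstruction_loss(x, imr)
                lrec_sum += lrec.item()
                lrec_steps += 1
            eff = LossWeights(
                w.lambda1 if lcls is not None else 0.0,
                w.lambda2 if lrec is not None else 0.0,
            ) if (lcls is not None or lrec is not None) else None
            if eff is None:
                continue
            loss = combined_loss(lcls, lrec, eff)
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_f1 = _val_macro_f1(model, ds, val_indices)
        history.append(
            {
                "epoch": epoch,
                "lcls": lcls_sum / lcls_steps if lcls_steps else None,
                "lrec": lrec_sum / lrec_steps if lrec_steps else None,
                "val_macro_f1": None if np.isnan(val_f1) else val_f1,
                "seed": cfg.seed,
            }
        )
        # checkpoint on strict improvement: ties keep the earliest epoch,
        # which doubles as early stopping when the labeled validation set
        # is small and its F1 takes few distinct values
        if not np.isnan(val_f1) and val_f1 > best_f1:
            best_f1 = val_f1
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if np.isfinite(best_f1):
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def evaluate_on_test(model: MultiTaskNet, test: LabeledDataset):
    """Predict every test item; returns (y_true, y_pred, Vp matrix)."""
    if not test.labeled_mask.all():
        raise ValueError("test set must be fully labeled")
    probs = model.predict_proba(test.images)
    return test.labels.copy(), predict_label(probs), probs


def write_history(history: list[dict], path) -> None:
    """Serialize the per-epoch history as JSON lines."""
    with open(path, "w") as fh:
        for row in history:
            fh.write(json.dumps(row) + "\n")
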