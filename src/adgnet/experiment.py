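"""Experiment orchestration: config, the full training/evaluation protocol,
and the phantom ablation benchmark.

``run_experiment`` executes the complete weakly supervised protocol on one
dataset: retain a stratified fraction of the labels, build stratified
cross-validation folds over the training-validation set, train one model per
fold, pick the model with the best validation macro-F1, and score it on the
held-out test set with bootstrap confidence intervals for all six metrics.
The emitted report is a plain JSON-serializable dict that is byte-identical
across runs with the same config and seed (modulo the timestamp).

``phantom_benchmark`` is the scaled-down ablation study on synthetic
phantoms: the full model versus the no-reconstruction-head and no-attention
variants, each trained from several seeds at a 20% label fraction.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .backbone import BackboneConfig
from .data import load_image_folder, load_nifti_dataset
from .heads import DecoderConfig
from .losses import FocalParams, LossWeights
from .metrics import bootstrap_ci, METRIC_NAMES, score_predictions
from .model import save_checkpoint
from .phantoms import PhantomSpec, PhantomSplit, generate_dataset
from .trainer import (
    LabeledDataset,
    TrainConfig,
    evaluate_on_test,
    make_folds,
    stratified_label_subset,
    train,
    write_history,
)

__all__ = ["RunConfig", "run_experiment", "phantom_benchmark", "benchmark_arm"]


@dataclass
class RunConfig:
    """Everything one experiment needs, loadable from YAML."""

    data_kind: str = "phantom"  # "phantom" | "image_folder" | "nifti"
    data_path: str | None = None
    target_size: tuple[int, ...] | None = None
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    bootstrap_B: int = 1000
    bootstrap_alpha: float = 0.05
    output_dir: str | None = None

    def __post_init__(self):
        if self.data_kind not in ("phantom", "image_folder", "nifti"):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")
        if self.data_kind != "phantom" and not self.data_path:
            raise ValueError(f"data_kind {self.data_kind!r} requires data_path")
        if self.target_size is not None:
            self.target_size = tuple(int(s) for s in self.target_size)
        # cross-component consistency
        if self.data_kind == "phantom":
            if self.phantom.shape != tuple(self.backbone.input_size):
                raise ValueError(
                    f"phantom shape {self.phantom.shape} != backbone input "
                    f"{self.backbone.input_size}"
                )
        elif self.target_size is not None and tuple(self.target_size) != tuple(
            self.backbone.input_size
        ):
            raise ValueError("target_size must equal the backbone input_size")
        if self.train.use_rsn:
            self.decoder.validate_against(self.backbone.input_size)

    # -- YAML -------------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**_tupled(kwargs["phantom"], "counts_per_class"))
        if "backbone" in kwargs:
            kwargs["backbone"] = BackboneConfig(
                **_tupled(kwargs["backbone"], "stage_channels", "blocks_per_stage", "input_size")
            )
        if "decoder" in kwargs:
            kwargs["decoder"] = DecoderConfig(**kwargs["decoder"])
        if "train" in kwargs:
            tr = dict(kwargs["train"])
            if "loss_weights" in tr:
                tr["loss_weights"] = LossWeights(**tr["loss_weights"])
            if "focal" in tr:
                tr["focal"] = FocalParams(**tr["focal"])
            kwargs["train"] = TrainConfig(**tr)
        if "target_size" in kwargs and kwargs["target_size"] is not None:
            kwargs["target_size"] = tuple(kwargs["target_size"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self), default=list))


def _tupled(d: dict, *keys: str) -> dict:
    d = dict(d)
    for k in keys:
        if k in d:
            d[k] = tuple(d[k])
    return d


def _load_split(cfg: RunConfig) -> tuple[LabeledDataset, LabeledDataset]:
    """Return (train-val set, test set) for the configured data source."""
    if cfg.data_kind == "phantom":
        split = generate_dataset(cfg.phantom)
        return split.tvs, split.ts
    if cfg.data_kind == "image_folder":
        ds = load_image_folder(cfg.data_path, cfg.target_size or (128, 128))
    else:
        ds = load_nifti_dataset(cfg.data_path, cfg.target_size or (32, 32, 32))
    # deterministic stratified 80/20 split for file-based datasets
    rng = np.random.default_rng(cfg.train.seed)
    ts_parts = []
    for c in range(ds.n_classes):
        members = np.flatnonzero(ds.labels == c)
        n_test = max(1, int(np.floor(0.2 * members.size + 0.5)))
        ts_parts.append(rng.choice(members, size=n_test, replace=False))
    ts_idx = np.sort(np.concatenate(ts_parts))
    tvs_idx = np.setdiff1d(np.arange(len(ds)), ts_idx)
    return ds.subset(tvs_idx), ds.subset(ts_idx)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with stage context."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, RuntimeError):
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_experiment(cfg: RunConfig, out_dir=None) -> dict:
    """Execute the full protocol and return the JSON-serializable report."""
    t0 = time.time()
    out_dir = Path(out_dir) if out_dir else (Path(cfg.output_dir) if cfg.output_dir else None)
    tcfg = cfg.train
    rng = np.random.default_rng(tcfg.seed)
    subset_seed = int(rng.integers(2**31))
    fold_seed = int(rng.integers(2**31))

    with _stage("load-data"):
        tvs, ts = _load_split(cfg)
    with _stage("label-subset"):
        tvs = stratified_label_subset(tvs, tcfg.label_fraction, subset_seed)
    with _stage("make-folds"):
        folds = make_folds(tvs, tcfg.folds, fold_seed)

    fold_records = []
    best = (-np.inf, None)  # (val f1, model)
    with _stage("train"):
        for fi, (tr_idx, va_idx) in enumerate(folds):
            fold_cfg = replace(tcfg, seed=int(tcfg.seed) + fi)
            model, history = train(
                tvs, fold_cfg, cfg.backbone, cfg.decoder, tr_idx, va_idx
            )
            va_labeled = va_idx[tvs.labeled_mask[va_idx]]
            val_scores = None
            val_f1 = -np.inf
            if va_labeled.size:
                from .heads import predict_label

                probs = model.predict_proba(tvs.images[va_labeled])
                val_scores = score_predictions(
                    tvs.labels[va_labeled], predict_label(probs), tvs.n_classes
                )
                val_f1 = val_scores["macro"]["f1"]
            fold_records.append(
                {
                    "fold": fi,
                    "n_train": int(tr_idx.size),
                    "n_val": int(va_idx.size),
                    "n_val_labeled": int(va_labeled.size),
                    "val": val_scores,
                    "final_lcls": history[-1]["lcls"] if history else None,
                    "final_lrec": history[-1]["lrec"] if history else None,
                }
            )
            if out_dir is not None:
                out_dir.mkdir(parents=True, exist_ok=True)
                write_history(history, out_dir / f"history_fold{fi}.jsonl")
            if val_f1 > best[0]:
                best = (val_f1, model)

    model = best[1]
    with _stage("evaluate"):
        y_true, y_pred, _ = evaluate_on_test(model, ts)
        test_scores = score_predictions(y_true, y_pred, ts.n_classes)
        cis = {}
        for m in METRIC_NAMES:
            try:
                r = bootstrap_ci(
                    y_true, y_pred, metric=m, B=cfg.bootstrap_B,
                    alpha=cfg.bootstrap_alpha, seed=tcfg.seed,
                )
            except ValueError:
                cis[m] = None
                continue
            cis[m] = {
                "point": r.point, "lower": r.lower, "upper": r.upper,
                "n_excluded": r.n_excluded,
            }

    report = {
        "config": cfg.to_dict(),
        "seed": tcfg.seed,
        "class_names": list(ts.class_names),
        "ablations": {"use_rsn": tcfg.use_rsn, "use_am": tcfg.use_am},
        "n_tvs": len(tvs),
        "n_labeled": int(tvs.labeled_mask.sum()),
        "n_test": len(ts),
        "folds": fold_records,
        "test": test_scores,
        "test_ci": cis,
        "bootstrap": {"B": cfg.bootstrap_B, "alpha": cfg.bootstrap_alpha},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "runtime_s": round(time.time() - t0, 3),
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        save_checkpoint(model, out_dir / "checkpoint.npz", extra={"seed": tcfg.seed})
    return report


# ---------------------------------------------------------------------------
# scaled-down phantom ablation benchmark
# ---------------------------------------------------------------------------

#: Benchmark study conditions: 500 two-class phantoms at 32x32 with the
#: calibrated severity/noise, 20% labels, reduced network widths.  Sized for
#: a single desktop CPU; see docs/methods.md.
BENCHMARK_PHANTOM = PhantomSpec(
    dimensionality=2,
    size=32,
    n_classes=2,
    severity_effect=0.6,
    noise_sd=0.2,
    counts_per_class=(250, 250),
    seed=2021,
)

BENCHMARK_BACKBONE = BackboneConfig(
    dimensionality=2,
    stage_channels=(8, 16, 16, 32, 32),
    blocks_per_stage=(1, 1, 1, 1, 1),
    attention_reduction=4,
    input_channels=1,
    input_size=(32, 32),
)

BENCHMARK_DECODER = DecoderConfig(
    M=5, base_size=1, base_channels=32, out_channels=1, dimensionality=2
)

BENCHMARK_TRAIN = TrainConfig(
    label_fraction=0.2,
    folds=5,
    epochs=15,
    batch_size=16,
    learning_rate=1e-3,
)


def benchmark_arm(
    split: PhantomSplit,
    seed: int,
    use_rsn: bool = True,
    use_am: bool = True,
    train_cfg: TrainConfig | None = None,
    backbone_cfg: BackboneConfig | None = None,
    decoder_cfg: DecoderConfig | None = None,
) -> float:
    """Train one configuration on the benchmark split; return test macro-F1."""
    tcfg = replace(
        train_cfg or BENCHMARK_TRAIN, seed=seed, use_rsn=use_rsn, use_am=use_am
    )
    bcfg = backbone_cfg or BENCHMARK_BACKBONE
    dcfg = decoder_cfg or BENCHMARK_DECODER
    rng = np.random.default_rng(seed)
    tvs = stratified_label_subset(split.tvs, tcfg.label_fraction, int(rng.integers(2**31)))
    tr_idx, va_idx = make_folds(tvs, tcfg.folds, int(rng.integers(2**31)))[0]
    model, _ = train(tvs, tcfg, bcfg, dcfg, tr_idx, va_idx)
    y_true, y_pred, _ = evaluate_on_test(model, split.ts)
    scores = score_predictions(y_true, y_pred, split.ts.n_classes)
    return scores["macro"]["f1"]


def phantom_benchmark(
    seeds=(0, 1, 2, 3, 4),
    arms=(("full", True, True), ("no_rsn", False, True), ("no_am", True, False)),
    spec: PhantomSpec | None = None,
    **kwargs,
) -> dict[str, list[float]]:
    """Test macro-F1 per ablation arm over several training seeds."""
    split = generate_dataset(spec or BENCHMARK_PHANTOM)
    results: dict[str, list[float]] = {}
    for name, use_rsn, use_am in arms:
        results[name] = [
            benchmark_arm(split, seed=s, use_rsn=use_rsn, use_am=use_am, **kwargs)
            for s in seeds
        ]
    return results
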