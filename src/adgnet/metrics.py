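"""Six-metric classifier evaluation with bootstrap confidence intervals.

For one positive class the confusion counts (TP, TN, FP, FN) yield

    p0    = (TP + TN) / N
    pe    = ((TN+FN)(TN+FP) + (TP+FP)(TP+FN)) / N^2
    kappa = (p0 - pe) / (1 - pe)          (chance-corrected agreement)
    sen   = TP / (TP + FN)                (sensitivity / recall)
    spe   = TN / (TN + FP)                (specificity)
    pr    = TP / (TP + FP)                (precision)
    acc   = (TP + TN) / N
    f1    = 2 * pr * sen / (pr + sen)

Multi-class problems are scored one-vs-rest per class and macro-averaged
(unweighted mean over classes, skipping classes where a metric is
undefined).  Any metric with a zero denominator is reported as 0 with its
``defined`` flag cleared — degenerate cases are flagged, never raised.

Uncertainty is quantified by a percentile bootstrap over (truth, prediction)
pairs: B resamples with replacement, the metric recomputed on each, and the
interval read off the empirical alpha/2 and 1-alpha/2 percentiles.
Resamples on which the metric is undefined are excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "METRIC_NAMES",
    "confusion_counts",
    "compute_metrics",
    "macro_average",
    "one_vs_rest_metrics",
    "score_predictions",
    "bootstrap_ci",
    "BootstrapResult",
]

METRIC_NAMES = ("kappa", "sen", "spe", "pr", "acc", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.n < 1:
            raise ValueError("total count must be >= 1")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricSet:
    """The six metrics plus per-metric definedness flags."""

    kappa: float
    sen: float
    spe: float
    pr: float
    acc: float
    f1: float
    defined: dict[str, bool] = field(
        default_factory=lambda: {m: True for m in METRIC_NAMES}
    )

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["defined"] = dict(self.defined)
        return d


def confusion_counts(y_true, y_pred, positive_class) -> ConfusionCounts:
    """One-vs-rest confusion counts (``positive_class`` vs everything else)."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1D sequences")
    if yt.size == 0:
        raise ValueError("empty label sequences")
    t = yt == positive_class
    p = yp == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (num / den, True) if den != 0 else (0.0, False)


def compute_metrics(cc: ConfusionCounts) -> MetricSet:
    """Evaluate all six metrics from one set of confusion counts."""
    tp, tn, fp, fn = cc.tp, cc.tn, cc.fp, cc.fn
    n = float(cc.n)
    p0 = (tp + tn) / n
    pe = ((tn + fn) * (tn + fp) + (tp + fp) * (tp + fn)) / (n * n)
    kappa, kappa_def = _ratio(p0 - pe, 1.0 - pe)
    sen, sen_def = _ratio(tp, tp + fn)
    spe, spe_def = _ratio(tn, tn + fp)
    pr, pr_def = _ratio(tp, tp + fp)
    acc = p0
    if pr_def and sen_def:
        f1, f1_def = _ratio(2.0 * pr * sen, pr + sen)
    else:
        f1, f1_def = 0.0, False
    return MetricSet(
        kappa=kappa, sen=sen, spe=spe, pr=pr, acc=acc, f1=f1,
        defined={
            "kappa": kappa_def, "sen": sen_def, "spe": spe_def,
            "pr": pr_def, "acc": True, "f1": f1_def,
        },
    )


def macro_average(per_class: list[MetricSet]) -> MetricSet:
    """Unweighted mean of each metric over classes, skipping undefined entries."""
    if not per_class:
        raise ValueError("macro_average needs at least one per-class MetricSet")
    values: dict[str, float] = {}
    defined: dict[str, bool] = {}
    for m in METRIC_NAMES:
        vals = [getattr(ms, m) for ms in per_class if ms.defined[m]]
        defined[m] = bool(vals)
        values[m] = float(np.mean(vals)) if vals else 0.0
    return MetricSet(**values, defined=defined)


def one_vs_rest_metrics(y_true, y_pred, classes) -> list[MetricSet]:
    """Per-class one-vs-rest MetricSets, in the order of ``classes``."""
    return [
        compute_metrics(confusion_counts(y_true, y_pred, c)) for c in classes
    ]


def score_predictions(y_true, y_pred, n_classes: int) -> dict:
    """Per-class and macro metrics as a plain dict (for reports)."""
    per_class = one_vs_rest_metrics(y_true, y_pred, range(n_classes))
    return {
        "per_class": [ms.as_dict() for ms in per_class],
        "macro": macro_average(per_class).as_dict(),
    }


@dataclass
class BootstrapResult:
    point: float
    lower: float
    upper: float
    samples: np.ndarray
    n_excluded: int

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _macro_metric(y_true, y_pred, metric: str, classes) -> tuple[float, bool]:
    ms = macro_average(one_vs_rest_metrics(y_true, y_pred, classes))
    return getattr(ms, metric), ms.defined[metric]


def bootstrap_ci(
    y_true,
    y_pred,
    metric: str = "f1",
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile bootstrap CI for a macro-averaged metric.

    Resamples the paired (truth, prediction) sequence with replacement;
    the model is never retrained.  Deterministic given ``seed``.
    """
    if metric not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1D sequences")
    classes = np.unique(yt)
    point, point_def = _macro_metric(yt, yp, metric, classes)
    if not point_def:
        raise ValueError(f"metric {metric!r} undefined on the full sample")
    rng = np.random.default_rng(seed)
    n = yt.size
    samples = []
    n_excluded = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        value, ok = _macro_metric(yt[idx], yp[idx], metric, classes)
        if ok:
            samples.append(value)
        else:
            n_excluded += 1
    samples = np.asarray(samples)
    lower, upper = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapResult(
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        samples=samples,
        n_excluded=n_excluded,
    )
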