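"""Evaluation-suite correctness: confusion counting against a brute-force
tally, the six-metric formulas against independent algebra and scikit-learn,
degenerate-case flagging, macro averaging, and the bootstrap machinery."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, f1_score, precision_score, recall_score

from adgnet.metrics import (
    BootstrapResult,
    ConfusionCounts,
    MetricSet,
    bootstrap_ci,
    compute_metrics,
    confusion_counts,
    macro_average,
    one_vs_rest_metrics,
)


class TestConfusionCounts:
    def test_simple_cases(self):
        cc = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0], 1)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (2, 2, 0, 0)
        cc = confusion_counts([1, 0], [0, 1], 1)
        assert (cc.tp, cc.tn, cc.fp, cc.fn) == (0, 0, 1, 1)

    def test_matches_brute_force_tally(self, rng):
        y_true = rng.integers(0, 3, size=1000)
        y_pred = rng.integers(0, 3, size=1000)
        for pos in range(3):
            cc = confusion_counts(y_true, y_pred, pos)
            tp = tn = fp = fn = 0
            for t, p in zip(y_true, y_pred):
                if t == pos and p == pos:
                    tp += 1
                elif t != pos and p != pos:
                    tn += 1
                elif t != pos and p == pos:
                    fp += 1
                else:
                    fn += 1
            assert (cc.tp, cc.tn, cc.fp, cc.fn) == (tp, tn, fp, fn)
            assert cc.n == 1000

    def test_validation(self):
        with pytest.raises(ValueError, match="equal-length"):
            confusion_counts([1, 0], [1], 1)
        with pytest.raises(ValueError, match="nonnegative"):
            ConfusionCounts(-1, 1, 1, 1)


class TestComputeMetrics:
    def test_worked_example(self):
        ms = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=5, fn=5))
        assert ms.acc == pytest.approx(0.9)
        assert ms.kappa == pytest.approx(0.79798, abs=1e-5)
        assert ms.sen == pytest.approx(0.90909, abs=1e-5)
        assert ms.spe == pytest.approx(0.88889, abs=1e-5)
        assert ms.pr == pytest.approx(0.90909, abs=1e-5)
        assert ms.f1 == pytest.approx(0.90909, abs=1e-5)
        assert all(ms.defined.values())

    def test_perfect_classifier_all_ones(self):
        ms = compute_metrics(ConfusionCounts(tp=10, tn=20, fp=0, fn=0))
        for m in ("kappa", "sen", "spe", "pr", "acc", "f1"):
            assert getattr(ms, m) == pytest.approx(1.0)

    def test_degenerate_precision_flagged(self):
        # everything predicted negative: no positive predictions
        ms = compute_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=2))
        assert ms.pr == 0.0 and not ms.defined["pr"]
        assert not ms.defined["f1"]
        assert ms.defined["acc"]

    def test_kappa_never_exceeds_accuracy(self, rng):
        for _ in range(2000):
            tp, tn, fp, fn = rng.integers(0, 50, size=4)
            if tp + tn + fp + fn == 0:
                continue
            ms = compute_metrics(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
            if ms.defined["kappa"]:
                assert ms.kappa <= ms.acc + 1e-12

    def test_symmetry_under_class_relabeling(self, rng):
        """Swapping TP<->TN with FP<->FN swaps sen and spe."""
        tp, tn, fp, fn = 12, 30, 4, 7
        a = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        b = compute_metrics(ConfusionCounts(tn, tp, fn, fp))
        assert a.sen == pytest.approx(b.spe)
        assert a.spe == pytest.approx(b.sen)
        assert a.acc == pytest.approx(b.acc)
        assert a.kappa == pytest.approx(b.kappa)

    def test_agrees_with_sklearn(self, rng):
        for _ in range(25):
            y_true = rng.integers(0, 2, size=200)
            y_pred = rng.integers(0, 2, size=200)
            if len(np.unique(y_true)) < 2 or len(np.unique(y_pred)) < 2:
                continue
            ms = compute_metrics(confusion_counts(y_true, y_pred, 1))
            assert ms.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)
            assert ms.sen == pytest.approx(recall_score(y_true, y_pred), abs=1e-12)
            assert ms.spe == pytest.approx(
                recall_score(y_true, y_pred, pos_label=0), abs=1e-12
            )
            assert ms.pr == pytest.approx(precision_score(y_true, y_pred), abs=1e-12)
            assert ms.f1 == pytest.approx(f1_score(y_true, y_pred), abs=1e-12)

    def test_f1_harmonic_mean_identity(self, rng):
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 30, size=4))
            if tp + tn + fp + fn == 0:
                continue
            ms = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            if ms.defined["f1"] and (ms.pr + ms.sen) > 0:
                assert ms.f1 == pytest.approx(
                    2 * ms.pr * ms.sen / (ms.pr + ms.sen), abs=1e-12
                )


class TestMacroAverage:
    def test_idempotent_on_identical_sets(self):
        ms = compute_metrics(ConfusionCounts(5, 5, 2, 3))
        out = macro_average([ms, ms, ms])
        for m in ("kappa", "sen", "spe", "pr", "acc", "f1"):
            assert getattr(out, m) == pytest.approx(getattr(ms, m))

    def test_arithmetic_and_undefined_exclusion(self):
        a = MetricSet(kappa=0, sen=0, spe=0, pr=0, acc=1, f1=1.0)
        b = MetricSet(kappa=0, sen=0, spe=0, pr=0, acc=0.5, f1=0.5)
        c = MetricSet(kappa=0, sen=0, spe=0, pr=0, acc=0.5, f1=0.0)
        c.defined["f1"] = False
        out = macro_average([a, b, c])
        assert out.f1 == pytest.approx(0.75)  # c's undefined f1 excluded
        assert out.acc == pytest.approx(2 / 3)

    def test_matches_brute_force_loop(self, rng):
        y_true = rng.integers(0, 4, size=300)
        y_pred = rng.integers(0, 4, size=300)
        per_class = one_vs_rest_metrics(y_true, y_pred, range(4))
        out = macro_average(per_class)
        for m in ("kappa", "sen", "spe", "pr", "acc", "f1"):
            vals = [getattr(ms, m) for ms in per_class if ms.defined[m]]
            assert getattr(out, m) == pytest.approx(np.mean(vals))

    def test_empty_list_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            macro_average([])


class TestBootstrap:
    def test_perfect_predictions_zero_width(self, rng):
        y = rng.integers(0, 2, size=80)
        for metric in ("f1", "acc", "sen"):
            r = bootstrap_ci(y, y.copy(), metric=metric, B=200, seed=1)
            assert (r.point, r.lower, r.upper) == (1.0, 1.0, 1.0)

    def test_same_seed_identical(self, rng):
        y_true = rng.integers(0, 2, size=100)
        y_pred = np.where(rng.uniform(size=100) < 0.85, y_true, 1 - y_true)
        a = bootstrap_ci(y_true, y_pred, B=300, seed=42)
        b = bootstrap_ci(y_true, y_pred, B=300, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_interval_orders_and_contains_point(self, rng):
        y_true = rng.integers(0, 2, size=200)
        y_pred = np.where(rng.uniform(size=200) < 0.9, y_true, 1 - y_true)
        r = bootstrap_ci(y_true, y_pred, metric="acc", B=500, seed=0)
        assert r.lower <= r.point <= r.upper
        assert r.n_excluded == 0

    def test_parameter_validation(self, rng):
        y = rng.integers(0, 2, size=10)
        with pytest.raises(ValueError, match="metric"):
            bootstrap_ci(y, y, metric="auc")
        with pytest.raises(ValueError, match="B"):
            bootstrap_ci(y, y, B=0)
        with pytest.raises(ValueError, match="alpha"):
            bootstrap_ci(y, y, alpha=1.5)
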