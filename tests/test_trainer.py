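"""Training-protocol contracts: stratified label retention, fold geometry,
gradient gating of the two heads, the irrelevance of unlabeled items to the
classification term, and pure evaluation."""

from dataclasses import replace

import numpy as np
import pytest

from adgnet.losses import LossWeights
from adgnet.model import MultiTaskNet
from adgnet.phantoms import PhantomSpec, generate_dataset
from adgnet.trainer import (
    LabeledDataset,
    TrainConfig,
    evaluate_on_test,
    make_folds,
    stratified_label_subset,
    train,
)


def _toy_dataset(counts, seed=0, size=32):
    spec = PhantomSpec(
        dimensionality=2, size=size, n_classes=len(counts),
        counts_per_class=tuple(counts), seed=seed,
    )
    return generate_dataset(spec).data


class TestStratifiedLabelSubset:
    def test_full_fraction_keeps_everything(self):
        ds = _toy_dataset((5, 5))
        out = stratified_label_subset(ds, 1.0, 0)
        assert out.labeled_mask.all()

    def test_rounding_rule_on_6_4(self):
        ds = _toy_dataset((6, 4))
        for seed in range(5):
            out = stratified_label_subset(ds, 0.2, seed)
            kept = np.bincount(out.labels[out.labeled_mask], minlength=2)
            np.testing.assert_array_equal(kept, [1, 1])

    def test_half_fraction_rounds_per_class(self):
        ds = _toy_dataset((7, 4))
        out = stratified_label_subset(ds, 0.5, 3)
        kept = np.bincount(out.labels[out.labeled_mask], minlength=2)
        np.testing.assert_array_equal(kept, [4, 2])  # round(3.5)->4, round(2)->2

    def test_deterministic_and_data_untouched(self):
        ds = _toy_dataset((8, 8))
        a = stratified_label_subset(ds, 0.25, 9)
        b = stratified_label_subset(ds, 0.25, 9)
        np.testing.assert_array_equal(a.labeled_mask, b.labeled_mask)
        np.testing.assert_array_equal(a.images, ds.images)
        np.testing.assert_array_equal(a.labels, ds.labels)

    def test_invalid_fraction(self):
        ds = _toy_dataset((4, 4))
        with pytest.raises(ValueError, match="fraction"):
            stratified_label_subset(ds, 0.0, 0)


class TestMakeFolds:
    def test_partition_and_balance(self):
        ds = _toy_dataset((50, 50))
        folds = make_folds(ds, 5, 0)
        all_val = np.concatenate([va for _, va in folds])
        assert sorted(all_val) == list(range(100))
        for tr, va in folds:
            assert set(tr) & set(va) == set()
            np.testing.assert_array_equal(np.bincount(ds.labels[va]), [10, 10])

    def test_two_folds_of_four_items(self):
        ds = _toy_dataset((2, 2))
        folds = make_folds(ds, 2, 1)
        for _, va in folds:
            np.testing.assert_array_equal(np.bincount(ds.labels[va], minlength=2), [1, 1])

    def test_deterministic(self):
        ds = _toy_dataset((10, 10))
        a = make_folds(ds, 5, 7)
        b = make_folds(ds, 5, 7)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)

    def test_small_class_rejected(self):
        ds = _toy_dataset((3, 10))
        with pytest.raises(ValueError, match=">= 5"):
            make_folds(ds, 5, 0)


@pytest.fixture(scope="module")
def small_ds():
    return _toy_dataset((8, 8), seed=5)


class TestTrainGating:
    """Zero loss weights must leave the corresponding head bit-identical."""

    def _init_params(self, cfg, backbone_cfg, decoder_cfg, n_classes=2):
        rng = np.random.default_rng(cfg.seed)
        init_seed = int(rng.integers(2**31))
        int(rng.integers(2**31))  # fold seed drawn next in train()
        from dataclasses import replace as _r

        return MultiTaskNet(
            _r(backbone_cfg, use_attention=cfg.use_am), n_classes,
            decoder_cfg if cfg.use_rsn else None, seed=init_seed,
        )

    def test_lambda1_zero_freezes_csn(self, small_ds, tiny_backbone_cfg, tiny_decoder_cfg):
        cfg = TrainConfig(
            label_fraction=1.0, epochs=2, batch_size=8, seed=0,
            loss_weights=LossWeights(0.0, 1.0),
        )
        idx = np.arange(len(small_ds))
        model, _ = train(small_ds, cfg, tiny_backbone_cfg, tiny_decoder_cfg, idx, idx)
        init = self._init_params(cfg, tiny_backbone_cfg, tiny_decoder_cfg)
        for p, q in zip(model.csn.parameters(), init.csn.parameters()):
            np.testing.assert_array_equal(p.data, q.data)
        moved = any(
            not np.array_equal(p.data, q.data)
            for p, q in zip(model.rsn_parameters(), init.rsn_parameters())
        )
        assert moved

    def test_lambda2_zero_freezes_decoder(self, small_ds, tiny_backbone_cfg, tiny_decoder_cfg):
        cfg = TrainConfig(
            label_fraction=1.0, epochs=2, batch_size=8, seed=0,
            loss_weights=LossWeights(1.0, 0.0),
        )
        idx = np.arange(len(small_ds))
        model, _ = train(small_ds, cfg, tiny_backbone_cfg, tiny_decoder_cfg, idx, idx)
        init = self._init_params(cfg, tiny_backbone_cfg, tiny_decoder_cfg)
        for p, q in zip(model.rsn_parameters(), init.rsn_parameters()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_no_rsn_allocates_no_decoder(self, small_ds, tiny_backbone_cfg, tiny_decoder_cfg):
        cfg = TrainConfig(label_fraction=1.0, epochs=1, batch_size=8, seed=0, use_rsn=False)
        idx = np.arange(len(small_ds))
        model, history = train(small_ds, cfg, tiny_backbone_cfg, tiny_decoder_cfg, idx, idx)
        assert model.decoder is None and model.encoder is None
        assert model.rsn_parameters() == []
        assert all(h["lrec"] is None for h in history)

    def test_unlabeled_items_never_influence_lcls(self, tiny_backbone_cfg, tiny_decoder_cfg):
        """With lambda2=0, dropping all unlabeled items entirely leaves the
        training trajectory identical (same seed)."""
        ds = _toy_dataset((10, 10), seed=2)
        masked = stratified_label_subset(ds, 0.5, seed=4)
        cfg = TrainConfig(
            label_fraction=1.0, epochs=2, batch_size=4, seed=3,
            loss_weights=LossWeights(1.0, 0.0), use_rsn=False, use_unlabeled=False,
        )
        idx_all = np.arange(len(masked))
        model_a, hist_a = train(masked, cfg, tiny_backbone_cfg, None, idx_all, idx_all)

        labeled_only = masked.subset(np.flatnonzero(masked.labeled_mask))
        idx_l = np.arange(len(labeled_only))
        model_b, hist_b = train(labeled_only, cfg, tiny_backbone_cfg, None, idx_l, idx_l)
        for ha, hb in zip(hist_a, hist_b):
            assert ha["lcls"] == pytest.approx(hb["lcls"], abs=1e-12)

    def test_no_labels_with_lambda1_raises(self, tiny_backbone_cfg):
        ds = _toy_dataset((4, 4))
        ds = LabeledDataset(ds.images, ds.labels, ds.class_names, np.zeros(8, bool))
        cfg = TrainConfig(label_fraction=1.0, epochs=1, seed=0, use_rsn=False)
        idx = np.arange(8)
        with pytest.raises(ValueError, match="labeled"):
            train(ds, cfg, tiny_backbone_cfg, None, idx, idx)


class TestEvaluateOnTest:
    def test_pure_and_shaped(self, tiny_backbone_cfg, small_phantom_split):
        model = MultiTaskNet(tiny_backbone_cfg, 2, None, seed=0)
        ts = small_phantom_split.ts
        before = {k: v.copy() for k, v in model.state_dict().items()}
        y_true1, y_pred1, vp1 = evaluate_on_test(model, ts)
        y_true2, y_pred2, vp2 = evaluate_on_test(model, ts)
        np.testing.assert_array_equal(y_pred1, y_pred2)
        np.testing.assert_array_equal(vp1, vp2)
        assert y_pred1.shape == (len(ts),)
        assert vp1.shape == (len(ts), 2)
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_unlabeled_test_rejected(self, tiny_backbone_cfg, small_phantom_split):
        model = MultiTaskNet(tiny_backbone_cfg, 2, None, seed=0)
        ts = small_phantom_split.ts
        broken = LabeledDataset(
            ts.images, ts.labels, ts.class_names,
            np.r_[np.zeros(1, bool), np.ones(len(ts) - 1, bool)],
        )
        with pytest.raises(ValueError, match="fully labeled"):
            evaluate_on_test(model, broken)

    def test_constant_model_predicts_argmax_class(self, tiny_backbone_cfg, small_phantom_split):
        model = MultiTaskNet(tiny_backbone_cfg, 2, None, seed=0)
        # force constant logits favoring class 0
        model.csn.fcp.weight.data[...] = 0
        model.csn.fcp.bias.data[...] = [2.0, -2.0]
        _, y_pred, vp = evaluate_on_test(model, small_phantom_split.ts)
        assert np.all(y_pred == 0)
        np.testing.assert_allclose(vp[:, 0], 1 / (1 + np.exp(-2)), rtol=1e-9)
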