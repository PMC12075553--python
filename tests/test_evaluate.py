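"""Metrics oracles, cross-validation protocol, ablation harness."""

import numpy as np
import pytest

import txclass
from txclass.cnn import ClassifierTrainConfig
from txclass.containers import DataError
from txclass.evaluate import (
    CVConfig,
    ablation_suite,
    confusion,
    cross_validate,
    metrics_from_confusion,
)
from txclass.wgan import CriticConfig, GeneratorConfig, WGANTrainConfig


def brute_force_counts(y_true, y_pred, n_classes):
    """Per-class one-vs-rest counts by explicit pairwise looping."""
    out = []
    for c in range(n_classes):
        tp = fp = tn = fn = 0
        for t, p in zip(y_true, y_pred):
            if t == c and p == c:
                tp += 1
            elif t != c and p == c:
                fp += 1
            elif t == c and p != c:
                fn += 1
            else:
                tn += 1
        out.append((tp, fp, fn, tn))
    return out


class TestConfusion:
    def test_perfect_predictions_have_no_errors(self):
        y = [0, 1, 2, 0, 1, 2]
        cc = confusion(y, y, 3)
        assert (cc.fp == 0).all() and (cc.fn == 0).all()
        assert cc.tp.sum() == 6

    def test_hand_enumerated_binary_example(self):
        cc = confusion([0, 0, 1, 1], [0, 1, 1, 1], 2)
        assert (cc.tp[0], cc.fn[0], cc.fp[0], cc.tn[0]) == (1, 1, 0, 2)
        assert (cc.tp[1], cc.fp[1], cc.fn[1], cc.tn[1]) == (2, 1, 0, 1)

    def test_matches_brute_force_loop_on_random_vectors(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        cc = confusion(y_true, y_pred, 3)
        for c, (tp, fp, fn, tn) in enumerate(brute_force_counts(y_true, y_pred, 3)):
            assert (cc.tp[c], cc.fp[c], cc.fn[c], cc.tn[c]) == (tp, fp, fn, tn)

    def test_counts_partition_the_sample(self):
        rng = np.random.default_rng(1)
        cc = confusion(rng.integers(0, 4, 150), rng.integers(0, 4, 150), 4)
        np.testing.assert_array_equal(cc.tp + cc.fp + cc.fn + cc.tn, 150)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(DataError, match="labels"):
            confusion([0, 3], [0, 1], 3)


class TestMetrics:
    def test_perfect_case_all_ones(self):
        rep = metrics_from_confusion(confusion([0, 1, 2] * 5, [0, 1, 2] * 5, 3))
        assert rep.accuracy == 1.0
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_macro_precision_of_hand_example(self):
        rep = metrics_from_confusion(confusion([0, 0, 1, 1], [0, 1, 1, 1], 2))
        assert rep.macro_precision == pytest.approx((1 / 1 + 2 / 3) / 2)

    def test_matches_sklearn_on_random_vectors(self):
        from sklearn.metrics import precision_recall_fscore_support

        rng = np.random.default_rng(2)
        for _ in range(20):
            y_true = rng.integers(0, 2, 100)
            y_pred = rng.integers(0, 2, 100)
            rep = metrics_from_confusion(confusion(y_true, y_pred, 2))
            p, r, f, _ = precision_recall_fscore_support(
                y_true, y_pred, average="macro", zero_division=0
            )
            assert rep.macro_precision == pytest.approx(p)
            assert rep.macro_recall == pytest.approx(r)
            assert rep.macro_f1 == pytest.approx(f)

    def test_accuracy_equals_elementwise_agreement(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, 500)
        y_pred = rng.integers(0, 3, 500)
        rep = metrics_from_confusion(confusion(y_true, y_pred, 3))
        assert rep.accuracy == pytest.approx(np.mean(y_true == y_pred))

    def test_macro_f1_bounded_by_per_class_f1(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 3, 200)
        y_pred = rng.integers(0, 3, 200)
        rep = metrics_from_confusion(confusion(y_true, y_pred, 3))
        assert rep.f1.min() - 1e-12 <= rep.macro_f1 <= rep.f1.max() + 1e-12

    def test_zero_denominator_reports_zero(self):
        # class 2 never predicted and never true -> precision/recall 0 by convention
        rep = metrics_from_confusion(confusion([0, 1], [0, 1], 3))
        assert rep.precision[2] == 0.0 and rep.recall[2] == 0.0 and rep.f1[2] == 0.0


FAST_CV = CVConfig(
    k=3,
    seed=0,
    augmenter="none",
    classifier="lda",
    target_per_class=40,
    gen_cfg=GeneratorConfig(noise_dim=8, layer_widths=(16, 16, 1)),
    critic_cfg=CriticConfig(layer_widths=(1, 16, 16, 1)),
    wgan_train=WGANTrainConfig(epochs=2, seed=0),
    clf_train=ClassifierTrainConfig(max_epochs=5, patience=3, seed=0),
)


class TestCrossValidate:
    def test_spiked_cohort_is_learnable_and_deterministic(self, tiny_cohort):
        cm, _ = tiny_cohort
        res = cross_validate(cm, FAST_CV)
        assert res.summary["f1"]["mean"] >= 0.9
        res2 = cross_validate(cm, FAST_CV)
        assert res.summary == res2.summary
        assert res.folds == res2.folds

    def test_folds_cover_all_samples_disjointly(self, tiny_cohort):
        cm, _ = tiny_cohort
        res = cross_validate(cm, FAST_CV)
        flat = [s for fold in res.folds for s in fold]
        assert sorted(flat) == sorted(cm.counts.columns)

    def test_k_larger_than_smallest_class_fails(self, tiny_cohort):
        cm, _ = tiny_cohort
        from dataclasses import replace

        with pytest.raises(DataError, match="fewer than k"):
            cross_validate(cm, replace(FAST_CV, k=21))

    def test_heldout_folds_contain_only_real_samples(self, tiny_cohort):
        """Audited inside cross_validate; predictions list original ids only."""
        cm, _ = tiny_cohort
        from dataclasses import replace

        res = cross_validate(cm, replace(FAST_CV, augmenter="smote"))
        assert set(res.predictions["sample_id"]) == set(cm.counts.columns)

    def test_unknown_options_rejected_with_valid_list(self):
        with pytest.raises(DataError, match="valid"):
            CVConfig(augmenter="bootstrap")
        with pytest.raises(DataError, match="valid"):
            CVConfig(selector="pca")
        with pytest.raises(DataError, match="valid"):
            CVConfig(classifier="transformer")


class TestAblation:
    def test_augmenter_swap_rows_share_fold_plan(self, tiny_cohort):
        cm, _ = tiny_cohort
        table = ablation_suite(cm, FAST_CV, augmenters=["none", "smote", "mixup"])
        assert len(table) == 3
        assert table["accuracy_mean"].notna().all()

    def test_baseline_classifier_suite_populates_all_metrics(self, tiny_cohort):
        cm, _ = tiny_cohort
        clfs = [
            "decision_tree",
            "knn",
            "lda",
            "naive_bayes",
            "random_forest",
            "svm",
            "logistic_regression",
        ]
        table = ablation_suite(cm, FAST_CV, classifiers=clfs)
        assert list(table["option"]) == clfs
        for col in ("accuracy_mean", "precision_mean", "recall_mean", "f1_mean"):
            assert table[col].between(0, 1).all()

    def test_selector_alternatives_run(self, tiny_cohort):
        from dataclasses import replace

        cm, _ = tiny_cohort
        cfg = replace(FAST_CV, n_features=30)
        table = ablation_suite(cm, cfg, selectors=["variance", "anova"])
        assert len(table) == 2
        assert table["f1_mean"].notna().all()
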