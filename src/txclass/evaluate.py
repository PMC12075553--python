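"""Confusion-matrix metrics and leakage-safe cross-validation.

Accuracy, precision, recall and F1 are computed from one-vs-rest counts of
the multiclass confusion matrix; multiclass summaries use macro (unweighted
class-mean) averaging. ``cross_validate`` runs the full pipeline inside
each training fold: differential-expression selection, transform statistics,
augmentation and classifier training all see only the k-1 training folds,
and held-out samples are scored after transformation with the frozen
training statistics. Held-out folds never contain synthetic rows; this is
audited on every fold. ``ablation_suite`` swaps the feature selector, the
augmenter or the classifier while keeping the fold plan fixed, so rows are
paired comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from txclass._random import subseed
from txclass.containers import CountMatrix, DataError, ExpressionMatrix
from txclass.cnn import ClassifierTrainConfig, CNNConfig, predict, train_classifier
from txclass.deg import (
    FeaturePanel,
    SelectionThresholds,
    estimate_size_factors,
    filter_expressed,
    run_deg,
)
from txclass.preprocess import make_folds, transform
from txclass.resample import resample_to_target
from txclass.wgan import (
    CriticConfig,
    GeneratorConfig,
    WGANTrainConfig,
    augment_to_target,
)

log = logging.getLogger(__name__)

AUGMENTERS = ("none", "wgan", "smote", "adasyn", "mixup")
SELECTORS = ("deseq", "variance", "mutual_info", "anova", "chi2")
CLASSIFIERS = (
    "cnn",
    "decision_tree",
    "knn",
    "lda",
    "naive_bayes",
    "random_forest",
    "svm",
    "logistic_regression",
)


@dataclass
class ConfusionCounts:
    """One-vs-rest TP/FP/TN/FN per class, plus the full matrix."""

    matrix: np.ndarray  # (n_classes, n_classes), rows = true, cols = predicted
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


@dataclass
class MetricsReport:
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
        }


def confusion(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest counts from the n_classes x n_classes confusion matrix."""
    yt = np.asarray(y_true, dtype=np.int64)
    yp = np.asarray(y_pred, dtype=np.int64)
    if yt.shape != yp.shape:
        raise DataError("y_true and y_pred must have equal length")
    if yt.size and (min(yt.min(), yp.min()) < 0 or max(yt.max(), yp.max()) >= n_classes):
        raise DataError(f"labels must lie in [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(mat, (yt, yp), 1)
    tp = np.diag(mat).astype(np.int64)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    tn = mat.sum() - tp - fp - fn
    return ConfusionCounts(mat, tp, fp, fn, tn)


def metrics_from_confusion(cc: ConfusionCounts) -> MetricsReport:
    """Accuracy and per-class / macro precision, recall, F1.

    Zero-denominator metrics are reported as 0 (with a warning), including
    F1 when precision + recall = 0.
    """
    n = cc.n
    accuracy = float(cc.tp.sum() / n) if n else 0.0

    def _safe(num, den, name):
        den = den.astype(np.float64)
        if (den == 0).any():
            log.warning("%s undefined for %d class(es); reporting 0", name, int((den == 0).sum()))
        return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

    precision = _safe(cc.tp, cc.tp + cc.fp, "precision")
    recall = _safe(cc.tp, cc.tp + cc.fn, "recall")
    pr = precision + recall
    f1 = np.where(pr > 0, 2.0 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    return MetricsReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        n=n,
    )


@dataclass(frozen=True)
class CVConfig:
    """Everything the cross-validated pipeline needs beyond the cohort."""

    thresholds: SelectionThresholds = SelectionThresholds()
    k: int = 5
    seed: int = 0
    selector: str = "deseq"
    n_features: int = 300  # panel size for the non-DE selectors
    augmenter: str = "wgan"
    target_per_class: int = 1000
    classifier: str = "cnn"
    global_panel: bool = False
    gen_cfg: GeneratorConfig = GeneratorConfig()
    critic_cfg: CriticConfig = CriticConfig()
    wgan_train: WGANTrainConfig = WGANTrainConfig()
    cnn_overrides: tuple = ()  # ((field, value), ...) applied to CNNConfig
    clf_train: ClassifierTrainConfig = ClassifierTrainConfig()
    ddof: int = 0

    def __post_init__(self) -> None:
        if self.selector not in SELECTORS:
            raise DataError(f"unknown selector {self.selector!r}; valid: {SELECTORS}")
        if self.augmenter not in AUGMENTERS:
            raise DataError(f"unknown augmenter {self.augmenter!r}; valid: {AUGMENTERS}")
        if self.classifier not in CLASSIFIERS:
            raise DataError(f"unknown classifier {self.classifier!r}; valid: {CLASSIFIERS}")


@dataclass
class CVResult:
    fold_metrics: list[MetricsReport]
    summary: dict[str, dict[str, float]]  # metric -> {mean, sd}
    predictions: pd.DataFrame
    folds: list[list[str]]
    panel_sizes: list[int]

    def summary_row(self) -> dict[str, float]:
        out = {}
        for metric, ms in self.summary.items():
            out[f"{metric}_mean"] = ms["mean"]
            out[f"{metric}_sd"] = ms["sd"]
        return out


def _alt_panel(train_cm: CountMatrix, cfg: CVConfig) -> FeaturePanel:
    """Filter-style selectors on log2 size-factor-normalized training counts."""
    from sklearn.feature_selection import chi2 as sk_chi2
    from sklearn.feature_selection import f_classif, mutual_info_classif

    expressed = filter_expressed(train_cm)
    sf = estimate_size_factors(expressed)
    x = np.log2(
        expressed.counts.to_numpy(dtype=np.float64) / sf.to_numpy()[None, :] + 1.0
    ).T
    y = expressed.labels.to_numpy()
    if cfg.selector == "variance":
        scores = x.var(axis=0)
    elif cfg.selector == "anova":
        scores, _ = f_classif(x, y)
    elif cfg.selector == "chi2":
        scores, _ = sk_chi2(x, y)
    elif cfg.selector == "mutual_info":
        scores = mutual_info_classif(x, y, random_state=subseed(cfg.seed, "mi"))
    else:  # pragma: no cover
        raise DataError(f"unknown selector {cfg.selector!r}")
    scores = np.where(np.isfinite(scores), scores, -np.inf)
    k = min(cfg.n_features, x.shape[1])
    top = np.argsort(-scores, kind="stable")[:k]
    genes = sorted(expressed.counts.index[top])
    return FeaturePanel(genes, {g: [cfg.selector] for g in genes})


def _augment(train_em: ExpressionMatrix, cfg: CVConfig, fold_seed: int) -> ExpressionMatrix:
    if cfg.augmenter == "none":
        return train_em
    if cfg.augmenter == "wgan":
        return augment_to_target(
            train_em,
            cfg.target_per_class,
            cfg.gen_cfg,
            cfg.critic_cfg,
            cfg.wgan_train,
            seed=fold_seed,
        )
    return resample_to_target(train_em, cfg.augmenter, cfg.target_per_class, seed=fold_seed)


def _sklearn_classifier(name: str, seed: int):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return {
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed),
        "knn": lambda: KNeighborsClassifier(),
        "lda": lambda: LinearDiscriminantAnalysis(),
        "naive_bayes": lambda: GaussianNB(),
        "random_forest": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "svm": lambda: SVC(random_state=seed),
        "logistic_regression": lambda: LogisticRegression(max_iter=2000, random_state=seed),
    }[name]()


def _fit_predict(
    train_em: ExpressionMatrix,
    test_em: ExpressionMatrix,
    cfg: CVConfig,
    fold_seed: int,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    classes = sorted(set(train_em.labels))
    if cfg.classifier == "cnn":
        overrides = dict(cfg.cnn_overrides)
        cnn_cfg = CNNConfig(
            in_length=train_em.n_features, n_classes=len(classes), **overrides
        )
        model, _ = train_classifier(
            train_em, cnn_cfg, replace(cfg.clf_train, seed=fold_seed)
        )
        labels, probs = predict(model, test_em.values)
        return labels, probs, classes
    clf = _sklearn_classifier(cfg.classifier, fold_seed)
    y = np.array([classes.index(c) for c in train_em.labels])
    clf.fit(train_em.values, y)
    pred_idx = clf.predict(test_em.values)
    labels = np.array([classes[i] for i in pred_idx], dtype=object)
    if hasattr(clf, "predict_proba"):
        probs = clf.predict_proba(test_em.values)
    else:
        probs = np.eye(len(classes))[pred_idx]
    return labels, probs, classes


def cross_validate(
    counts: CountMatrix, cfg: CVConfig = CVConfig(), folds: list[list[str]] | None = None
) -> CVResult:
    """Stratified k-fold evaluation of the full pipeline; see module docs.

    With ``cfg.global_panel`` the feature panel is selected once on all
    samples (the optimistic single-selection protocol some studies use);
    by default selection happens inside each training fold.
    """
    if folds is None:
        folds = make_folds(counts.labels, cfg.k, subseed(cfg.seed, "folds"))
    all_ids = set(counts.counts.columns)

    global_panel: FeaturePanel | None = None
    if cfg.global_panel:
        if cfg.selector == "deseq":
            _, global_panel, _, _ = run_deg(counts, cfg.thresholds)
        else:
            global_panel = _alt_panel(counts, cfg)

    fold_metrics: list[MetricsReport] = []
    pred_rows = []
    panel_sizes = []
    for fi, test_ids in enumerate(folds):
        test_set = set(test_ids)
        if not test_set <= all_ids:
            raise DataError(f"fold {fi} references unknown samples")
        train_ids = [s for s in counts.counts.columns if s not in test_set]
        train_cm = counts.subset_samples(train_ids)
        test_cm = counts.subset_samples(test_ids)
        fold_seed = subseed(cfg.seed, "fold", fi)

        if global_panel is not None:
            panel = global_panel
        elif cfg.selector == "deseq":
            _, panel, _, _ = run_deg(train_cm, cfg.thresholds)
        else:
            panel = _alt_panel(train_cm, cfg)
        panel_sizes.append(len(panel))

        train_em, stats = transform(train_cm, panel)
        train_em = _augment(train_em, cfg, fold_seed)
        test_em, _ = transform(test_cm, panel, stats=stats)

        # audit: the held-out fold is original samples only, never synthetic
        assert set(test_em.samples) == test_set
        assert (test_em.provenance == "real").all()

        labels, probs, classes = _fit_predict(train_em, test_em, cfg, fold_seed)
        y_true = np.array([classes.index(c) for c in test_em.labels])
        y_pred = np.array(
            [classes.index(c) if c in classes else -1 for c in labels]
        )
        if (y_pred < 0).any():
            raise DataError("prediction outside the training label set")
        cc = confusion(y_true, y_pred, len(classes))
        fold_metrics.append(metrics_from_confusion(cc))
        for sid, t, p, pr in zip(test_em.samples, test_em.labels, labels, probs):
            row = {"sample_id": sid, "fold": fi, "true": t, "predicted": p}
            for ci, cls in enumerate(classes):
                row[f"p_{cls}"] = float(pr[ci])
            pred_rows.append(row)

    summary = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([m.as_dict()[metric] for m in fold_metrics])
        summary[metric] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=cfg.ddof)),
        }
    return CVResult(fold_metrics, summary, pd.DataFrame(pred_rows), folds, panel_sizes)


def ablation_suite(
    counts: CountMatrix,
    base_cfg: CVConfig = CVConfig(),
    selectors: list[str] | None = None,
    augmenters: list[str] | None = None,
    classifiers: list[str] | None = None,
) -> pd.DataFrame:
    """Paired comparison table over selector / augmenter / classifier swaps.

    Every row reruns cross-validation with one component changed from
    ``base_cfg``; the fold plan is derived from the shared seed, so all rows
    score identical held-out folds.
    """
    folds = make_folds(counts.labels, base_cfg.k, subseed(base_cfg.seed, "folds"))
    variants: list[tuple[str, str, CVConfig]] = []
    for sel in selectors or []:
        if sel not in SELECTORS:
            raise DataError(f"unknown selector {sel!r}; valid: {SELECTORS}")
        variants.append(("selector", sel, replace(base_cfg, selector=sel)))
    for aug in augmenters or []:
        if aug not in AUGMENTERS:
            raise DataError(f"unknown augmenter {aug!r}; valid: {AUGMENTERS}")
        variants.append(("augmenter", aug, replace(base_cfg, augmenter=aug)))
    for clf in classifiers or []:
        if clf not in CLASSIFIERS:
            raise DataError(f"unknown classifier {clf!r}; valid: {CLASSIFIERS}")
        variants.append(("classifier", clf, replace(base_cfg, classifier=clf)))
    if not variants:
        variants.append(("baseline", "baseline", base_cfg))

    rows = []
    for component, value, cfg in variants:
        result = cross_validate(counts, cfg, folds=folds)
        row = {"component": component, "option": value}
        row.update(result.summary_row())
        rows.append(row)
    return pd.DataFrame(rows)
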