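"""Panel subsetting, log / z-score transformation, and stratified fold plans.

The transform is log2(count / size_factor + 1) per gene and sample, followed
by per-feature z-scoring. Z-score statistics are always computed on training
samples and frozen; applying them to held-out samples never refits, which is
the leakage-safe protocol for cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from txclass.containers import CountMatrix, DataError, ExpressionMatrix, TransformStats
from txclass.deg import log_geomeans, size_factors_from_reference
from txclass.deg import FeaturePanel

log = logging.getLogger(__name__)


def transform(
    counts: CountMatrix,
    panel: FeaturePanel,
    sf: pd.Series | None = None,
    stats: TransformStats | None = None,
) -> tuple[ExpressionMatrix, TransformStats]:
    """Standardized expression over the panel; fits or applies frozen stats.

    With ``stats=None`` (training), size factors may be supplied or are
    estimated internally, and per-feature mean/sd are computed from the given
    samples and returned frozen. With ``stats`` supplied (held-out samples),
    size factors are computed against the frozen training log-geomean
    reference and the stored mean/sd are applied unchanged.

    Features with zero training variance are dropped with a warning; the
    returned stats list only the retained features.
    """
    missing = [g for g in panel.genes if g not in counts.counts.index]
    if missing:
        raise DataError(f"panel gene missing from count matrix: {missing[0]!r}")

    if stats is not None:
        features = stats.features
        sub = counts.counts.loc[features]
        factors = size_factors_from_reference(
            counts.counts, stats.log_geomeans
        ) / np.exp(stats.sf_log_scale)
        x = np.log2(sub.to_numpy(dtype=np.float64) / factors[None, :] + 1.0).T
        z = (x - stats.mean[None, :]) / stats.sd[None, :]
        em = ExpressionMatrix(
            z, list(counts.counts.columns), list(features), counts.labels.to_numpy()
        )
        return em, stats

    if sf is None:
        from txclass.deg import estimate_size_factors, filter_expressed

        sf = estimate_size_factors(filter_expressed(counts))
    factors = sf.reindex(counts.counts.columns).to_numpy()
    sub = counts.counts.loc[panel.genes]
    x = np.log2(sub.to_numpy(dtype=np.float64) / factors[None, :] + 1.0).T
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(panel.genes, keep) if not k]
        log.warning(
            "dropping %d zero-variance panel feature(s): %s",
            len(dropped),
            dropped[:5],
        )
    features = [g for g, k in zip(panel.genes, keep) if k]
    if not features:
        raise DataError("every panel feature has zero training variance")
    lg = log_geomeans(counts.counts)
    raw = size_factors_from_reference(counts.counts, lg)
    frozen = TransformStats(
        features=features,
        mean=mean[keep],
        sd=sd[keep],
        log_geomeans=lg,
        sf_log_scale=float(np.mean(np.log(raw)) - np.mean(np.log(factors))),
    )
    z = (x[:, keep] - frozen.mean[None, :]) / frozen.sd[None, :]
    em = ExpressionMatrix(
        z, list(counts.counts.columns), features, counts.labels.to_numpy()
    )
    return em, frozen


def make_folds(labels: pd.Series, k: int = 5, seed: int = 0) -> list[list[str]]:
    """Stratified k-fold plan: k disjoint held-out sample-id lists.

    Class proportions per fold are within one sample of the global
    proportions; deterministic given ``seed``.
    """
    if k < 2:
        raise DataError("k must be >= 2 (k=1 leaves no held-out data)")
    counts = labels.value_counts()
    too_small = counts[counts < k]
    if not too_small.empty:
        raise DataError(
            f"class {too_small.index[0]!r} has {int(too_small.iloc[0])} samples, "
            f"fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(labels.index)
    folds = []
    for _, test_idx in skf.split(ids, labels.to_numpy()):
        folds.append([str(s) for s in ids[test_idx]])
    return folds
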