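"""Classical oversampling comparators for the ablation harness.

Small self-contained implementations of SMOTE, ADASYN and within-class
MIXUP over z-scored expression rows, sharing the augment-to-target contract
of the WGAN stage: each class is brought up to a target count, real rows
pass through unchanged, synthetic rows are flagged in provenance.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

from txclass._random import substream
from txclass.containers import DataError, ExpressionMatrix


def _interpolate(rows: np.ndarray, base_idx: np.ndarray, nbr_idx: np.ndarray, rng) -> np.ndarray:
    lam = rng.random((len(base_idx), 1))
    return rows[base_idx] + lam * (rows[nbr_idx] - rows[base_idx])


def smote_rows(rows: np.ndarray, n_new: int, rng: np.random.Generator, k: int = 5) -> np.ndarray:
    """kNN line-segment interpolation within one class."""
    if len(rows) < 2:
        return np.repeat(rows, n_new, axis=0)[:n_new]
    k_eff = min(k, len(rows) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(rows)
    _, nbrs = nn.kneighbors(rows)
    base = rng.integers(0, len(rows), size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)  # skip self at column 0
    return _interpolate(rows, base, nbrs[base, pick], rng)


def adasyn_rows(
    rows: np.ndarray,
    other: np.ndarray,
    n_new: int,
    rng: np.random.Generator,
    k: int = 5,
) -> np.ndarray:
    """SMOTE-style interpolation, density-weighted toward borderline samples.

    Each minority row's weight is the fraction of its k nearest neighbours
    (among all samples) that belong to other classes.
    """
    if len(rows) < 2:
        return np.repeat(rows, n_new, axis=0)[:n_new]
    pool = np.vstack([rows, other])
    is_other = np.concatenate([np.zeros(len(rows), bool), np.ones(len(other), bool)])
    k_eff = min(k, len(pool) - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(pool)
    _, nbrs = nn.kneighbors(rows)
    ratio = is_other[nbrs[:, 1:]].mean(axis=1)
    if ratio.sum() == 0:
        weights = np.full(len(rows), 1.0 / len(rows))
    else:
        weights = ratio / ratio.sum()
    base = rng.choice(len(rows), size=n_new, p=weights)
    k_in = min(k, len(rows) - 1)
    nn_in = NearestNeighbors(n_neighbors=k_in + 1).fit(rows)
    _, nbrs_in = nn_in.kneighbors(rows)
    pick = rng.integers(1, k_in + 1, size=n_new)
    return _interpolate(rows, base, nbrs_in[base, pick], rng)


def mixup_rows(rows: np.ndarray, n_new: int, rng: np.random.Generator) -> np.ndarray:
    """Convex combinations of random same-class pairs, lambda ~ U(0, 1)."""
    if len(rows) < 2:
        return np.repeat(rows, n_new, axis=0)[:n_new]
    i = rng.integers(0, len(rows), size=n_new)
    j = rng.integers(0, len(rows), size=n_new)
    lam = rng.random((n_new, 1))
    return lam * rows[i] + (1.0 - lam) * rows[j]


def resample_to_target(
    train_data: ExpressionMatrix,
    method: str,
    target_per_class: int,
    seed: int = 0,
) -> ExpressionMatrix:
    """Bring every class to ``target_per_class`` rows with a classical method."""
    if method not in ("smote", "adasyn", "mixup"):
        raise DataError(f"unknown resampling method {method!r}")
    classes = sorted(set(train_data.labels))
    values = [train_data.values]
    samples = list(train_data.samples)
    labels = list(train_data.labels)
    provenance = list(train_data.provenance)
    for cls in classes:
        rows = train_data.rows_for_class(cls)
        shortfall = target_per_class - len(rows)
        if shortfall <= 0:
            continue
        rng = substream(seed, "resample", method, cls)
        if method == "smote":
            synth = smote_rows(rows, shortfall, rng)
        elif method == "adasyn":
            other = train_data.values[train_data.labels != cls]
            synth = adasyn_rows(rows, other, shortfall, rng)
        else:
            synth = mixup_rows(rows, shortfall, rng)
        values.append(synth)
        samples.extend(f"{cls}_syn_{i + 1:04d}" for i in range(shortfall))
        labels.extend([cls] * shortfall)
        provenance.extend(["synthetic"] * shortfall)
    return ExpressionMatrix(
        np.vstack(values),
        samples,
        list(train_data.features),
        np.asarray(labels, dtype=object),
        np.asarray(provenance, dtype=object),
    )
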