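"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class CountMatrix:
    """Raw negative-binomial counts, genes x samples, with class labels.

    ``counts`` has gene ids as the index and sample ids as columns;
    ``labels`` maps sample id -> class name and must cover every column.
    """

    counts: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise DataError(f"duplicated gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise DataError(f"duplicated sample id: {dup!r}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise DataError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise DataError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.labels.index]
        if missing:
            raise DataError(f"samples without labels: {missing[:5]}")
        orphans = [s for s in self.labels.index if s not in self.counts.columns]
        if orphans:
            raise DataError(f"labels reference absent samples: {orphans[:5]}")
        self.labels = self.labels.reindex(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(self.labels.unique())

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.labels.loc[list(sample_ids)])

    def class_members(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])


@dataclass
class TransformStats:
    """Frozen per-feature transform statistics (fit on training data only).

    ``features`` lists the retained panel genes in order; features whose
    training standard deviation was zero are dropped at fit time and are
    absent here.
    """

    features: list[str]
    mean: np.ndarray
    sd: np.ndarray
    log_geomeans: pd.Series  # per-gene log geometric means of the training
    # counts, the frozen reference for size-factor estimation on new samples
    sf_log_scale: float = 0.0  # frozen log rescaling constant that centered
    # the training size factors to geometric mean 1

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            raise DataError("transform stats contain non-positive sd")


@dataclass
class ExpressionMatrix:
    """Samples x panel-features real matrix, log-transformed and z-scored."""

    values: np.ndarray
    samples: list[str]
    features: list[str]
    labels: np.ndarray  # class name per row
    provenance: np.ndarray = field(default=None)  # "real" | "synthetic" per row

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples), len(self.features)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.features)} features"
            )
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.samples):
            raise DataError("one label per sample required")
        if self.provenance is None:
            self.provenance = np.full(len(self.samples), "real", dtype=object)
        self.provenance = np.asarray(self.provenance, dtype=object)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows_for_class(self, cls: str) -> np.ndarray:
        return self.values[self.labels == cls]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.samples, columns=self.features)
        df.insert(0, "class", self.labels)
        df.insert(1, "provenance", self.provenance)
        return df
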