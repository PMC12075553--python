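"""Synthetic multi-class RNA-seq cohort simulator with known DE ground truth.

Counts are drawn from a negative binomial parameterized by mean ``mu`` and
dispersion ``alpha`` (variance = mu + alpha * mu**2, the convention used by
the DE stage), with per-sample library-size factors and a configurable
fraction of spiked genes carrying a known log2 fold change per pairwise
contrast. Spiked genes are disjoint between contrasts and split half
up- / half down-regulated, so recall against the truth table is unambiguous.

The default class sizes (100 normal, 553 classA, 600 classB) echo the
imbalance of typical TCGA lung-cancer cohorts (LUSC 553 vs LUAD 600 tumor
samples plus a smaller normal arm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from txclass._random import substream
from txclass.containers import CountMatrix, DataError

#: class names in label order: the normal arm and the two tumor analogues.
CLASS_NAMES = ("normal", "classA", "classB")

#: pairwise contrasts as (reference, alternative); log2FC is alt over ref.
CONTRASTS = (
    ("normal", "classA"),
    ("normal", "classB"),
    ("classA", "classB"),
)


def contrast_id(ref: str, alt: str) -> str:
    return f"{ref}_vs_{alt}"


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``baseline_log_mean_range`` is an interval on the natural-log scale from
    which per-gene baseline means are drawn log-uniformly;
    ``libsize_factor_range`` likewise (on the natural scale) for per-sample
    library-size factors. ``dispersion`` is the NB alpha shared by all genes;
    alpha = 0 gives the Poisson limit.
    """

    n_genes: int = 2000
    class_sizes: tuple[int, int, int] = (100, 553, 600)
    baseline_log_mean_range: tuple[float, float] = (math.log(5.0), math.log(1000.0))
    dispersion: float = 0.1
    spike_fraction: float = 0.05
    spike_log2fc: float = 3.0
    libsize_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise DataError("n_genes must be positive")
        if len(self.class_sizes) != 3 or any(n <= 0 for n in self.class_sizes):
            raise DataError("class_sizes must be three positive counts")
        if self.dispersion < 0:
            raise DataError("dispersion must be >= 0")
        if not 0.0 <= self.spike_fraction <= 1.0:
            raise DataError("spike_fraction must lie in [0, 1]")
        lo, hi = self.libsize_factor_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise DataError("libsize_factor_range must be a positive interval")
        if 3 * self.n_spiked_per_contrast > self.n_genes:
            raise DataError("spike_fraction too large: spiked blocks must be disjoint")

    @property
    def n_spiked_per_contrast(self) -> int:
        return int(round(self.spike_fraction * self.n_genes))


@dataclass
class TruthTable:
    """Per-gene, per-contrast ground truth: DE flag and true log2FC.

    The table is derived from the per-class log2 offsets actually used to
    simulate means, so a gene spiked for one contrast that incidentally
    shifts another contrast's means is recorded as DE there too.
    """

    table: pd.DataFrame = field(repr=False)  # columns: gene, contrast, is_de, true_log2fc

    def for_contrast(self, cid: str) -> pd.DataFrame:
        sub = self.table[self.table["contrast"] == cid]
        if sub.empty:
            raise KeyError(f"unknown contrast {cid!r}")
        return sub.set_index("gene")

    def de_genes(self, cid: str) -> list[str]:
        sub = self.for_contrast(cid)
        return list(sub.index[sub["is_de"]])

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _sample_ids(class_sizes) -> tuple[list[str], list[str]]:
    ids, labels = [], []
    for cls, size in zip(CLASS_NAMES, class_sizes):
        for i in range(size):
            ids.append(f"{cls}_{i + 1:04d}")
            labels.append(cls)
    return ids, labels


def _spike_offsets(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-gene, per-class log2 offsets implementing the spiked contrasts.

    Each contrast receives a disjoint block of genes whose offset is applied
    to the contrast's alternative class: the first half of the block +lfc
    (up in the alternative), the second half -lfc.
    """
    offsets = np.zeros((spec.n_genes, len(CLASS_NAMES)), dtype=np.float64)
    n_spike = spec.n_spiked_per_contrast
    if n_spike == 0:
        return offsets
    order = rng.permutation(spec.n_genes)
    for ci, (_, alt) in enumerate(CONTRASTS):
        block = order[ci * n_spike : (ci + 1) * n_spike]
        col = CLASS_NAMES.index(alt)
        half = n_spike // 2
        offsets[block[:half], col] = spec.spike_log2fc
        offsets[block[half:], col] = -spec.spike_log2fc
    return offsets


def simulate_counts(spec: CohortSpec) -> tuple[CountMatrix, TruthTable]:
    """Draw a cohort from the NB model of ``spec``; deterministic given seed.

    Returns the labelled count matrix and the truth table listing, for every
    gene and pairwise contrast, whether it is DE and its exact log2 fold
    change (``+-spike_log2fc`` for spiked genes, 0 otherwise). Genes whose
    simulated counts happen to be all zero are kept; the DE stage filters
    them.
    """
    rng = substream(spec.seed, "sim_cohort")
    genes = _gene_ids(spec.n_genes)
    samples, labels = _sample_ids(spec.class_sizes)
    n_samples = len(samples)

    lo, hi = spec.baseline_log_mean_range
    base_mu = np.exp(rng.uniform(lo, hi, size=spec.n_genes))
    sf = np.exp(
        rng.uniform(
            math.log(spec.libsize_factor_range[0]),
            math.log(spec.libsize_factor_range[1]),
            size=n_samples,
        )
    )
    offsets = _spike_offsets(spec, rng)

    class_idx = np.array([CLASS_NAMES.index(c) for c in labels])
    # mean[g, s] = sf_s * mu_g * 2**offset[g, class(s)]
    mu = base_mu[:, None] * np.exp2(offsets[:, class_idx]) * sf[None, :]
    alpha = spec.dispersion
    if alpha == 0.0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / alpha
        counts = rng.negative_binomial(r, 1.0 / (1.0 + alpha * mu))

    cm = CountMatrix(
        pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples),
        pd.Series(labels, index=samples, name="class"),
    )

    rows = []
    for ref, alt in CONTRASTS:
        cid = contrast_id(ref, alt)
        lfc = offsets[:, CLASS_NAMES.index(alt)] - offsets[:, CLASS_NAMES.index(ref)]
        for g, v in zip(genes, lfc):
            rows.append((g, cid, v != 0.0, float(v)))
    truth = TruthTable(
        pd.DataFrame(rows, columns=["gene", "contrast", "is_de", "true_log2fc"])
    )
    return cm, truth
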