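"""Negative-binomial differential expression and union feature-panel selection.

The engine follows the standard count-data workflow: median-of-ratios size
factors, a per-gene method-of-moments dispersion estimate, and a per-gene NB
generalized linear model (log link, intercept + group indicator, log size
factors as offsets) tested with a Wald statistic, followed by
Benjamini-Hochberg adjustment within each contrast. It deliberately omits
the dispersion-trend shrinkage, outlier filtering and independent filtering
of full DESeq2-style pipelines: the contract here is the dual-threshold
(|log2FC|, adjusted p) selection and the union panel across the three
pairwise contrasts.

The GLM is fit by Newton scoring vectorized across genes; each iteration
solves all genes' 2x2 systems at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from txclass.containers import CountMatrix, DataError
from txclass.sim import CONTRASTS, contrast_id

log = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-8
MAX_NEWTON_ITER = 50
NEWTON_TOL = 1e-8
#: |coefficient| (natural-log scale) beyond which the fit is declared divergent
BETA_DIVERGED = 20.0


@dataclass(frozen=True)
class SelectionThresholds:
    """Dual selection thresholds: |log2FC| > lfc_min and padj < alpha."""

    lfc_min: float = 2.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_min <= 0:
            raise DataError("lfc_min must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must lie in (0, 1)")


@dataclass
class FeaturePanel:
    """Ordered union of genes passing both thresholds in >= 1 contrast."""

    genes: list[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise DataError("feature panel contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


def filter_expressed(counts: CountMatrix) -> CountMatrix:
    """Drop genes with zero counts across all samples."""
    keep = counts.counts.sum(axis=1) > 0
    return CountMatrix(counts.counts.loc[keep], counts.labels)


def log_geomeans(counts: pd.DataFrame) -> pd.Series:
    """Per-gene mean of log counts over samples (log geometric mean).

    Genes with any zero count get -inf and are excluded from the
    median-of-ratios downstream, matching the standard estimator.
    """
    with np.errstate(divide="ignore"):
        lg = np.log(counts.to_numpy(dtype=np.float64))
    return pd.Series(lg.mean(axis=1), index=counts.index)


def size_factors_from_reference(
    counts: pd.DataFrame, reference: pd.Series
) -> np.ndarray:
    """Median-of-ratios factors against a frozen log-geomean reference.

    Used both for training samples (reference computed from themselves) and
    for held-out samples scored against the training reference, so test
    normalization never sees test data statistics.
    """
    ref = reference.reindex(counts.index).to_numpy()
    usable = np.isfinite(ref)
    mat = counts.to_numpy(dtype=np.float64)
    factors = np.empty(mat.shape[1])
    with np.errstate(divide="ignore"):
        logc = np.log(mat)
    for j in range(mat.shape[1]):
        log_ratios = logc[usable, j] - ref[usable]
        log_ratios = log_ratios[np.isfinite(log_ratios)]
        if log_ratios.size == 0:
            raise DataError(
                "cannot estimate a size factor: no gene is expressed in every "
                "sample; pre-filter low-count genes"
            )
        factors[j] = np.median(np.exp(log_ratios))
    return factors


def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """DESeq-style median-of-ratios size factors, geometric-mean centered.

    factor_s = median over genes (expressed in all samples) of
    count[g, s] / geomean_g(count), rescaled so the factors' geometric mean
    is 1.
    """
    ref = log_geomeans(counts.counts)
    if not np.isfinite(ref).any():
        raise DataError(
            "no gene has nonzero counts in every sample; pre-filter the matrix"
        )
    factors = size_factors_from_reference(counts.counts, ref)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.counts.columns, name="size_factor")


def estimate_dispersions(counts: CountMatrix, sf: pd.Series) -> pd.Series:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Group means are removed before pooling, so spiked between-group signal
    does not inflate the estimate:
    alpha_g = max((s2_g - mbar_g) / mbar_g**2, floor) with s2_g the pooled
    within-group variance and mbar_g the overall normalized mean.
    """
    sf = sf.reindex(counts.counts.columns)
    norm = counts.counts.to_numpy(dtype=np.float64) / sf.to_numpy()[None, :]
    labels = counts.labels.to_numpy()
    groups = np.unique(labels)
    n = norm.shape[1]
    resid = np.empty_like(norm)
    for g in groups:
        mask = labels == g
        if mask.sum() < 2:
            raise DataError(f"group {g!r} has fewer than 2 samples")
        resid[:, mask] = norm[:, mask] - norm[:, mask].mean(axis=1, keepdims=True)
    s2 = (resid**2).sum(axis=1) / (n - len(groups))
    mbar = norm.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - mbar) / mbar**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=counts.counts.index, name="dispersion")


def _nb_two_group_wald(
    y: np.ndarray, sf: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Newton scoring for y_gs ~ NB(sf_s * exp(b0_g + b1_g * x_s)).

    Returns (beta1, se1, converged); beta on the natural-log scale.
    """
    n_genes, n_samples = y.shape
    # moment-based start: per-group normalized means with a half pseudocount
    norm = y / sf[None, :]
    m0 = norm[:, x == 0].mean(axis=1)
    m1 = norm[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(m0, 0.5 / n_samples))
    b1 = np.log(np.maximum(m1, 0.5 / n_samples)) - b0

    active = np.ones(n_genes, dtype=bool)
    converged = np.zeros(n_genes, dtype=bool)
    lsf = np.log(sf)
    for _ in range(MAX_NEWTON_ITER):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = b0[idx, None] + b1[idx, None] * x[None, :] + lsf[None, :]
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        denom = 1.0 + alpha[idx, None] * mu
        w = mu / denom  # NB working weights for the log link
        r = (y[idx] - mu) / denom  # score residuals
        s0 = r.sum(axis=1)
        s1 = (r * x[None, :]).sum(axis=1)
        i00 = w.sum(axis=1)
        i01 = (w * x[None, :]).sum(axis=1)
        i11 = i01  # x is 0/1 so x**2 == x
        det = i00 * i11 - i01 * i01
        ok = det > 1e-12
        det = np.where(ok, det, 1.0)
        d0 = (i11 * s0 - i01 * s1) / det
        d1 = (i00 * s1 - i01 * s0) / det
        d0 = np.where(ok, np.clip(d0, -5.0, 5.0), 0.0)
        d1 = np.where(ok, np.clip(d1, -5.0, 5.0), 0.0)
        b0[idx] += d0
        b1[idx] += d1
        done = (np.abs(d0) < NEWTON_TOL) & (np.abs(d1) < NEWTON_TOL) & ok
        diverged = (np.abs(b1[idx]) > BETA_DIVERGED) | ~ok
        converged[idx[done]] = True
        active[idx[done | diverged]] = False

    # standard errors from the final Fisher information
    eta = b0[:, None] + b1[:, None] * x[None, :] + lsf[None, :]
    eta = np.clip(eta, -50.0, 50.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    i00 = w.sum(axis=1)
    i01 = (w * x[None, :]).sum(axis=1)
    det = np.maximum(i00 * i01 - i01 * i01, 1e-300)
    se1 = np.sqrt(np.maximum(i00 / det, 0.0))
    return b1, se1, converged


def wald_test_pair(
    counts: CountMatrix,
    sf: pd.Series,
    dispersions: pd.Series,
    group_ref: str,
    group_alt: str,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group_alt`` vs ``group_ref``.

    Returns a DataFrame with columns gene, contrast, log2FC, wald_stat,
    pvalue, padj, converged; log2FC is the group coefficient divided by
    ln 2 (positive = higher in ``group_alt``). Non-converged fits are
    reported conservatively with p = 1 and a pseudocount-based log2FC.
    Genes with all-zero counts must already have been removed.
    """
    members = [
        s
        for s in counts.counts.columns
        if counts.labels[s] in (group_ref, group_alt)
    ]
    for grp in (group_ref, group_alt):
        if (counts.labels[members] == grp).sum() < 2:
            raise DataError(f"group {grp!r} needs >= 2 samples")
    sub = counts.counts[members]
    if (sub.sum(axis=1) == 0).any():
        raise DataError("remove genes with all-zero counts before testing")
    y = sub.to_numpy(dtype=np.float64)
    sfa = sf.reindex(members).to_numpy()
    x = (counts.labels[members] == group_alt).to_numpy(dtype=np.float64)
    alpha = dispersions.reindex(sub.index).to_numpy()

    b1, se1, converged = _nb_two_group_wald(y, sfa, x, alpha)
    n_fail = int((~converged).sum())
    if n_fail:
        log.warning(
            "%d/%d genes did not converge in %s vs %s; their p is set to 1",
            n_fail,
            len(b1),
            group_ref,
            group_alt,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se1
    z = np.where(np.isfinite(z), z, 0.0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))

    # fallback effect size for divergent fits: 0.5-pseudocount group means
    norm = y / sfa[None, :]
    lfc_pseudo = np.log2(norm[:, x == 1].mean(axis=1) + 0.5) - np.log2(
        norm[:, x == 0].mean(axis=1) + 0.5
    )
    log2fc = np.where(converged, b1 / np.log(2.0), lfc_pseudo)
    pvals = np.where(converged, pvals, 1.0)
    z = np.where(converged, z, 0.0)

    out = pd.DataFrame(
        {
            "gene": sub.index,
            "contrast": contrast_id(group_ref, group_alt),
            "log2FC": log2fc,
            "wald_stat": z,
            "pvalue": pvals,
            "padj": bh_adjust(pvals),
            "converged": converged,
        }
    )
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise DataError("p_values must be one-dimensional")
    if np.isnan(p).any():
        raise DataError("p_values contain NaN")
    if ((p < 0) | (p > 1)).any():
        raise DataError("p_values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def select_panel(
    contrast_tables: list[pd.DataFrame],
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> FeaturePanel:
    """Union panel: genes passing both thresholds in at least one contrast.

    Both comparisons are strict (|log2FC| > lfc_min, padj < alpha). The
    panel is sorted by gene id; provenance records which contrast(s)
    selected each member.
    """
    provenance: dict[str, list[str]] = {}
    for table in contrast_tables:
        hits = table[
            (table["log2FC"].abs() > thresholds.lfc_min)
            & (table["padj"] < thresholds.alpha)
        ]
        for gene, cid in zip(hits["gene"], hits["contrast"]):
            provenance.setdefault(gene, [])
            if cid not in provenance[gene]:
                provenance[gene].append(cid)
    if not provenance:
        raise DataError(
            "no gene passed the selection thresholds in any contrast; "
            "downstream stages need at least one feature"
        )
    genes = sorted(provenance)
    return FeaturePanel(genes, {g: provenance[g] for g in genes})


def run_deg(
    counts: CountMatrix,
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> tuple[dict[str, pd.DataFrame], FeaturePanel, pd.Series, pd.Series]:
    """Full DE stage: filter, normalize, test the three contrasts, select.

    Returns (per-contrast tables, panel, size factors, dispersions).
    Runs on raw counts with offsets; transformation happens downstream,
    after panel subsetting.
    """
    expressed = filter_expressed(counts)
    sf = estimate_size_factors(expressed)
    disp = estimate_dispersions(expressed, sf)
    tables: dict[str, pd.DataFrame] = {}
    present = set(expressed.labels.unique())
    for ref, alt in CONTRASTS:
        if ref not in present or alt not in present:
            raise DataError(f"contrast group missing from labels: {ref} / {alt}")
        tables[contrast_id(ref, alt)] = wald_test_pair(expressed, sf, disp, ref, alt)
    panel = select_panel(list(tables.values()), thresholds)
    return tables, panel, sf, disp
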