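# Methods

## Statistical model of the cohort simulator

Counts are drawn as `c_gj ~ NB(mean = s_j * mu_g * 2^(delta_gc), dispersion
alpha)` with variance `mu + alpha * mu^2` (the parameterization the DE stage
estimates, so simulator and test share one model). Per-gene baseline means
`mu_g` are log-uniform on [5, 1000] — spanning low- to high-expressed genes
— and per-sample library-size factors `s_j` are log-uniform on [0.5, 2] so
that size-factor estimation is genuinely exercised. The shared dispersion
defaults to `alpha = 0.1`, a typical bulk RNA-seq magnitude; `alpha = 0`
gives the Poisson limit used by the calibration tests.

Differential expression is spiked per pairwise contrast: a disjoint block of
`spike_fraction * n_genes` genes (default 5%) receives a log2 offset of
`+-spike_log2fc` (default 3, half up / half down) on the contrast's
alternative class. The truth table records the log2FC every contrast
actually sees — a gene offset on one tumor class is truthfully flagged DE in
both contrasts involving that class — so recall and false-discovery rates
are unambiguous. Default class sizes (100 normal, 553 and 600 tumor
samples) mirror the imbalance of public lung-cancer cohorts; the normal arm
is a free parameter because real normal-arm sizes vary by cohort.

What the simulator does **not** model: gene–gene correlation, batch
effects, per-gene dispersion heterogeneity, or any exosomal biology. Passing
tests therefore demonstrate that each stage implements its contract under
its own statistical assumptions, not that the pipeline attains any
particular accuracy on real tumor data.

## Differential expression engine

Median-of-ratios size factors are computed against the per-gene log
geometric means (genes with any zero count are excluded from the reference;
the natural-scale median is taken, and factors are rescaled to geometric
mean 1). Dispersion is a per-gene method of moments on normalized counts
with group means removed before pooling, floored at 1e-8:
`alpha_g = max((s^2_g - mbar_g) / mbar_g^2, 1e-8)`.

Each contrast fits, per gene, the NB GLM `log mu = beta_0 + beta_1 x + log
s_j` by Newton scoring vectorized across genes (every iteration solves all
2×2 Fisher systems at once; steps are clipped to ±5 per iteration, at most
50 iterations, convergence at 1e-8). `log2FC = beta_1 / ln 2`; the Wald
statistic is referred to the standard normal. Fits that diverge
(`|beta_1| > 20` or a singular information matrix) are flagged, reported
with `p = 1` (conservative) and a 0.5-pseudocount moment log2FC.
Benjamini–Hochberg adjustment is applied within each contrast, matching the
per-analysis convention of standard DE tools. This engine deliberately
omits dispersion-trend shrinkage, outlier-based filtering, independent
filtering and lfc shrinkage: the package's contract is the dual-threshold
union-panel selection with a faithful NB Wald core, and the simplified
engine is validated per-gene against an independent GLM implementation in
the test suite. Both selection inequalities are strict (`|log2FC| > 2`,
`padj < 0.05`).

## Transform and fold protocol

Expression is `log2(count / s_j + 1)` followed by per-feature z-scoring.
All transform statistics — the per-gene log-geomean reference for test-fold
size factors, its centering constant, and the feature means/sds — are fit
on training samples only and frozen; held-out samples are transformed with
the frozen statistics, never refit. Features with zero training variance
are dropped with a warning. Folds are stratified, seeded, and disjoint;
this per-fold protocol is the leakage-safe default, while a `global_panel`
option reproduces the optimistic single-selection protocol (selecting the
panel once on all samples) for comparison.

## WGAN augmenter

One WGAN per class, trained on that class's z-scored training rows — the
classifier's input space, so synthetic and real rows are directly
comparable. Generator: noise (100-d standard normal by default) →
512 → 1024 → panel width, LeakyReLU(0.2) between layers, linear output
(z-scores are unbounded). Critic: panel → 512 → 256 → 1, linear output
(a Wasserstein critic score is unbounded). Training: RMSprop at 1e-4,
batch 16, 200 epochs, 5 critic steps per generator step, and every critic
parameter clipped into [-0.01, 0.01] after each update — the clipping bound
is asserted in-loop by the tests. Per-class training (rather than a
conditional GAN) is the simplest mechanism consistent with class-wise
balancing; classes at or above the target pass through unchanged and real
rows are preserved bitwise. When a class is smaller than the batch size the
batch shrinks to the class size (logged).

## 1D CNN classifier

Three conv blocks (16 channels, kernel 3, same padding → batch-norm → ReLU
→ max-pool 2) — the block count is configurable so a single-block reading
of the architecture is one flag away. The spatial-attention gate follows
the channel-pool pattern: per-position channel mean and max are stacked,
convolved (kernel 7, same padding) and squashed by a sigmoid into a gate in
(0,1) multiplying every channel. Dropout 0.5 sits before the
fully-connected head (one hidden layer of 64). Training uses cross-entropy
with Adam (1e-3, batch 16), an internal stratified 20% validation split,
early stopping with patience 10 (cap 200 epochs), and restores the
best-validation parameters. Class imbalance is handled only by
augmentation, never by loss weighting.

The layer library underneath (`txclass.nn`) is a deliberate part of the
package: float64 numpy with hand-written backward passes, verified against
central-difference gradients in the tests, which keeps every forward and
training run deterministic given the seed on a single CPU.

## Evaluation

Metrics come from one-vs-rest counts of the multiclass confusion matrix;
multiclass summaries are macro averages (the standard choice for imbalance
studies), zero-denominator cases report 0 with a warning, and cross-
validation aggregates mean ± population standard deviation (ddof
configurable) over folds. Held-out folds are scored on original samples
only; an in-loop audit asserts no synthetic row is ever scored. The
ablation harness swaps the selector (variance / ANOVA F / chi-squared /
mutual information on log-normalized counts, top-k), the augmenter (none /
SMOTE / ADASYN / within-class MIXUP — small in-package implementations over
k-nearest-neighbour interpolation), or the classifier (seven classical
baselines) while reusing one fold plan, so all rows are paired comparisons.

## Numerical and design choices

- All randomness flows from one seed through CRC32-tagged substreams;
  changing one stage's stream leaves the others (e.g. the fold plan) intact.
- Ties in `argmax` predictions break toward the lower class index; BH is
  computed by the step-up cumulative-minimum form; strict inequalities at
  both selection thresholds.
- Genes that are all-zero across samples are removed before size-factor
  estimation; all-zero within one group is handled by the divergence path
  of the Wald fit.
- Problem sizes in the tests and the acceptance script (cohorts of ~2000
  genes, hundreds of samples, reduced training epochs) were chosen as the
  smallest scales at which every contract is meaningfully exercised; the
  spiked cohorts they use are strongly separable by construction, so
  near-perfect cross-validated scores are the expected behaviour, not a
  claim about real cohorts.

## Known limitations

- The NB Wald engine is anti-conservative relative to shrinkage-based DE
  tools at very small sample sizes (no dispersion moderation).
- Weight-clipped WGANs are the least stable WGAN variant; the defaults are
  tuned for the low-dimensional panels produced by DE selection, and no
  gradient-penalty or spectral-norm variant is provided.
- No batch-effect correction or cross-cohort harmonization: external
  validation support is limited to frozen-stats transform + predict.
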