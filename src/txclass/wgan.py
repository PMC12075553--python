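"""Per-class Wasserstein-GAN oversampling of expression vectors.

One independent WGAN is trained per minority class on that class's
(z-scored) training rows. Generator and critic are fully-connected
LeakyReLU stacks; the critic is kept approximately 1-Lipschitz by clipping
every parameter into [-c, c] after each update. Training alternates
``n_critic`` critic steps per generator step under RMSprop, following the
standard WGAN recipe: learning rate 1e-4, batch size 16, 200 epochs,
clip 0.01. Each class is expanded to a target count (default 1000); real
rows pass through bitwise unchanged and synthetic rows are flagged in the
provenance column.

Default widths: generator 100 -> 512 -> 1024 -> panel, critic
panel -> 512 -> 256 -> 1; the generator output layer is linear because the
data are unbounded z-scores, and the critic output is linear because a
Wasserstein critic score is unbounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist, pdist

from txclass._random import substream
from txclass.containers import DataError, ExpressionMatrix
from txclass.nn import LeakyReLU, Linear, RMSprop, Sequential, clip_params

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Fully-connected generator: noise -> hidden widths -> panel size."""

    noise_dim: int = 100
    layer_widths: tuple[int, ...] = (512, 1024, 2960)  # last entry = panel size
    slope: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_dim < 1:
            raise DataError("noise_dim must be >= 1")
        if not self.layer_widths or any(w < 1 for w in self.layer_widths):
            raise DataError("layer_widths must be positive")

    @property
    def out_dim(self) -> int:
        return self.layer_widths[-1]

    def for_panel(self, n_features: int) -> "GeneratorConfig":
        return replace(self, layer_widths=(*self.layer_widths[:-1], n_features))


@dataclass(frozen=True)
class CriticConfig:
    """Fully-connected critic: panel size -> hidden widths -> scalar score."""

    layer_widths: tuple[int, ...] = (2960, 512, 256, 1)
    slope: float = 0.2

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2 or any(w < 1 for w in self.layer_widths):
            raise DataError("layer_widths must be positive with >= 2 entries")
        if self.layer_widths[-1] != 1:
            raise DataError("critic must end in a single scalar score")

    @property
    def in_dim(self) -> int:
        return self.layer_widths[0]

    def for_panel(self, n_features: int) -> "CriticConfig":
        return replace(self, layer_widths=(n_features, *self.layer_widths[1:]))


@dataclass(frozen=True)
class WGANTrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    epochs: int = 200
    clip_value: float = 0.01
    n_critic: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clip_value <= 0:
            raise DataError("clip_value must be positive")
        if min(self.batch_size, self.n_critic) < 1 or self.epochs < 0:
            raise DataError("batch_size, n_critic must be >= 1 and epochs >= 0")


def build_generator(cfg: GeneratorConfig, rng: np.random.Generator) -> Sequential:
    layers = []
    widths = (cfg.noise_dim, *cfg.layer_widths)
    for i in range(len(widths) - 1):
        layers.append(Linear(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2:
            layers.append(LeakyReLU(cfg.slope))
    return Sequential(layers)


def build_critic(cfg: CriticConfig, rng: np.random.Generator) -> Sequential:
    layers = []
    widths = cfg.layer_widths
    for i in range(len(widths) - 1):
        layers.append(Linear(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2:
            layers.append(LeakyReLU(cfg.slope))
    return Sequential(layers)


def critic_loss(critic: Sequential, real_batch: np.ndarray, fake_batch: np.ndarray) -> float:
    """-(mean D(real) - mean D(fake)): minimizing it maximizes the critic objective."""
    if real_batch.shape[1] != fake_batch.shape[1]:
        raise DataError("real and fake batches differ in width")
    if len(real_batch) == 0 or len(fake_batch) == 0:
        raise DataError("batches must be nonempty")
    d_real = critic.forward(real_batch, train=False).mean()
    d_fake = critic.forward(fake_batch, train=False).mean()
    return float(-(d_real - d_fake))


def generator_loss(critic: Sequential, fake_batch: np.ndarray) -> float:
    """-mean D(fake): minimized when the critic scores fakes like reals."""
    if len(fake_batch) == 0:
        raise DataError("batch must be nonempty")
    return float(-critic.forward(fake_batch, train=False).mean())


def generate(
    generator: Sequential, n: int, seed: int, noise_dim: int | None = None
) -> np.ndarray:
    """Draw n synthetic rows from the generator; deterministic given seed."""
    if n <= 0:
        raise DataError("n must be positive")
    if noise_dim is None:
        first = generator.layers[0]
        noise_dim = first.w.value.shape[0]
    rng = substream(seed, "wgan_generate")
    z = rng.standard_normal((n, noise_dim))
    return generator.forward(z, train=False)


def train_wgan(
    real: np.ndarray,
    gcfg: GeneratorConfig,
    ccfg: CriticConfig,
    tcfg: WGANTrainConfig,
    on_critic_step=None,
) -> tuple[Sequential, Sequential, list[dict]]:
    """Adversarial training on one class's rows; returns (G, D, history).

    Each batch performs one critic update (RMSprop step then parameter
    clipping); after every ``n_critic`` critic updates the generator takes
    one step. ``on_critic_step``, if given, is called with the critic's
    parameter list after every clip (used by the invariant checks).
    """
    real = np.asarray(real, dtype=np.float64)
    n, d = real.shape
    if gcfg.out_dim != d or ccfg.in_dim != d:
        raise DataError(
            f"config width mismatch: data {d}, generator {gcfg.out_dim}, "
            f"critic {ccfg.in_dim}"
        )
    batch_size = tcfg.batch_size
    if batch_size > n:
        log.info("class has %d rows < batch size %d; shrinking batch", n, batch_size)
        batch_size = n

    init_rng = substream(tcfg.seed, "wgan_init")
    gen = build_generator(gcfg, init_rng)
    critic = build_critic(ccfg, init_rng)
    g_opt = RMSprop(gen.params(), tcfg.learning_rate)
    d_opt = RMSprop(critic.params(), tcfg.learning_rate)
    rng = substream(tcfg.seed, "wgan_train")

    history: list[dict] = []
    critic_steps = 0
    for epoch in range(tcfg.epochs):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - batch_size + 1, batch_size):
            rb = real[perm[start : start + batch_size]]
            z = rng.standard_normal((batch_size, gcfg.noise_dim))
            fake = gen.forward(z, train=False)

            critic.zero_grad()
            out_r = critic.forward(rb, train=True)
            critic.backward(np.full_like(out_r, -1.0 / len(out_r)))
            out_f = critic.forward(fake, train=True)
            critic.backward(np.full_like(out_f, 1.0 / len(out_f)))
            d_opt.step()
            clip_params(critic.params(), tcfg.clip_value)
            if on_critic_step is not None:
                on_critic_step(critic.params())
            epoch_losses.append(float(-(out_r.mean() - out_f.mean())))
            critic_steps += 1

            if critic_steps % tcfg.n_critic == 0:
                z = rng.standard_normal((batch_size, gcfg.noise_dim))
                gen.zero_grad()
                fake = gen.forward(z, train=True)
                critic.zero_grad()
                out_f = critic.forward(fake, train=True)
                dfake = critic.backward(np.full_like(out_f, -1.0 / len(out_f)))
                gen.backward(dfake)
                g_opt.step()
        history.append(
            {"epoch": epoch, "critic_loss": float(np.mean(epoch_losses)) if epoch_losses else np.nan}
        )
    return gen, critic, history


def energy_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample energy distance 2 E|x-y| - E|x-x'| - E|y-y'| (Euclidean)."""
    exy = cdist(x, y).mean()
    exx = 0.0 if len(x) < 2 else 2.0 * pdist(x).sum() / (len(x) * len(x))
    eyy = 0.0 if len(y) < 2 else 2.0 * pdist(y).sum() / (len(y) * len(y))
    return float(2.0 * exy - exx - eyy)


def augment_to_target(
    train_data: ExpressionMatrix,
    target_per_class: int = 1000,
    gcfg: GeneratorConfig = GeneratorConfig(),
    ccfg: CriticConfig = CriticConfig(),
    tcfg: WGANTrainConfig = WGANTrainConfig(),
    seed: int = 0,
) -> ExpressionMatrix:
    """Balance classes by synthesizing each class's shortfall with its WGAN.

    Classes already at or above ``target_per_class`` pass through unchanged
    (no real row is ever discarded). Real rows are preserved bitwise and
    come first, in their input order; synthetic rows are appended per class
    with a ``synthetic`` provenance flag.
    """
    classes = sorted(set(train_data.labels))
    sizes = {c: int((train_data.labels == c).sum()) for c in classes}
    if min(sizes.values()) == 0:
        raise DataError("every class must be nonempty")
    if target_per_class < max(sizes.values()):
        log.warning(
            "target %d below largest class size %d; larger classes pass through",
            target_per_class,
            max(sizes.values()),
        )
    d = train_data.n_features
    gcfg = gcfg.for_panel(d)
    ccfg = ccfg.for_panel(d)

    values = [train_data.values]
    samples = list(train_data.samples)
    labels = list(train_data.labels)
    provenance = list(train_data.provenance)
    for cls in classes:
        shortfall = target_per_class - sizes[cls]
        if shortfall <= 0:
            continue
        rows = train_data.rows_for_class(cls)
        cls_seed = substream(seed, "wgan_class", cls).integers(0, 2**31 - 1)
        gen, _, _ = train_wgan(rows, gcfg, ccfg, replace(tcfg, seed=int(cls_seed)))
        synth = generate(gen, shortfall, int(cls_seed))
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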