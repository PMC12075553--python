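"""WGAN: losses, clipping invariant, toy recovery, balancing contract."""

import numpy as np
import pytest

from txclass._random import substream
from txclass.containers import DataError, ExpressionMatrix
from txclass.wgan import (
    CriticConfig,
    GeneratorConfig,
    WGANTrainConfig,
    augment_to_target,
    build_generator,
    critic_loss,
    energy_distance,
    generate,
    generator_loss,
    train_wgan,
)

TOY_GEN = GeneratorConfig(noise_dim=8, layer_widths=(32, 32, 2))
TOY_CRITIC = CriticConfig(layer_widths=(2, 32, 32, 1))


class _StubCritic:
    """Critic returning pre-assigned scores keyed by batch identity."""

    def __init__(self, mapping):
        self.mapping = mapping

    def forward(self, x, train):
        return self.mapping[id(x)]


class TestLosses:
    def test_constant_critic_gives_zero_loss(self):
        real = np.zeros((3, 2))
        fake = np.ones((4, 2))
        critic = _StubCritic({id(real): np.full((3, 1), 7.0), id(fake): np.full((4, 1), 7.0)})
        assert critic_loss(critic, real, fake) == pytest.approx(0.0)

    def test_direct_evaluation_of_formulas(self):
        real = np.zeros((2, 2))
        fake = np.ones((2, 2))
        critic = _StubCritic({id(real): np.array([[1.0], [1.0]]), id(fake): np.array([[0.0], [0.0]])})
        assert critic_loss(critic, real, fake) == pytest.approx(-1.0)
        assert generator_loss(critic, fake) == pytest.approx(0.0)

    def test_swapping_batches_negates_critic_loss(self):
        rng = np.random.default_rng(0)
        real = rng.normal(size=(5, 2))
        fake = rng.normal(size=(5, 2))
        critic = build_generator(GeneratorConfig(noise_dim=2, layer_widths=(8, 8, 1)), rng)
        assert critic_loss(critic, real, fake) == pytest.approx(
            -critic_loss(critic, fake, real)
        )

    def test_width_mismatch_rejected(self):
        critic = _StubCritic({})
        with pytest.raises(DataError, match="width"):
            critic_loss(critic, np.zeros((2, 3)), np.zeros((2, 4)))


class TestGenerate:
    def test_output_has_panel_dimensionality(self):
        rng = substream(0, "t")
        gen = build_generator(GeneratorConfig().for_panel(2960), rng)
        out = generate(gen, 5, seed=0)
        assert out.shape == (5, 2960)

    def test_same_seed_reproduces_output(self):
        rng = substream(1, "t")
        gen = build_generator(TOY_GEN, rng)
        np.testing.assert_array_equal(generate(gen, 10, seed=3), generate(gen, 10, seed=3))
        assert not np.array_equal(generate(gen, 10, seed=3), generate(gen, 10, seed=4))

    def test_nonpositive_n_rejected(self):
        rng = substream(1, "t")
        gen = build_generator(TOY_GEN, rng)
        with pytest.raises(DataError):
            generate(gen, 0, seed=0)


class TestTraining:
    def _toy_real(self, n=256):
        rng = substream(0, "toy_data")
        return rng.normal(0.0, 1.0, (n, 2)) + np.array([3.0, -2.0])

    def test_critic_weights_clipped_after_every_update(self):
        real = self._toy_real(64)
        seen = []
        train_wgan(
            real,
            TOY_GEN,
            TOY_CRITIC,
            WGANTrainConfig(epochs=3, seed=0),
            on_critic_step=lambda ps: seen.append(
                max(float(np.abs(p.value).max()) for p in ps)
            ),
        )
        assert seen and max(seen) <= 0.01 + 1e-12

    def test_toy_training_moves_toward_target_distribution(self):
        real = self._toy_real()
        tcfg = WGANTrainConfig(epochs=100, seed=0)
        gen, _, history = train_wgan(real, TOY_GEN, TOY_CRITIC, tcfg)
        gen0 = build_generator(TOY_GEN, substream(0, "wgan_init"))
        pre = generate(gen0, 400, seed=9)
        post = generate(gen, 400, seed=9)
        assert energy_distance(post, real) < energy_distance(pre, real)
        assert len(history) == 100
        # trained mean is closer to (3, -2) than the untrained one
        target = np.array([3.0, -2.0])
        assert np.linalg.norm(post.mean(0) - target) < np.linalg.norm(pre.mean(0) - target)

    def test_zero_epochs_returns_initialization(self):
        real = self._toy_real(32)
        gen, _, history = train_wgan(real, TOY_GEN, TOY_CRITIC, WGANTrainConfig(epochs=0, seed=5))
        gen0 = build_generator(TOY_GEN, substream(5, "wgan_init"))
        for a, b in zip(gen.state_arrays(), gen0.state_arrays()):
            np.testing.assert_array_equal(a, b)
        assert history == []

    def test_width_mismatch_rejected(self):
        with pytest.raises(DataError, match="mismatch"):
            train_wgan(np.zeros((8, 3)), TOY_GEN, TOY_CRITIC, WGANTrainConfig(epochs=1))


class TestAugment:
    def _em(self, sizes=(12, 30, 30), d=20, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.concatenate([[c] * n for c, n in zip("abc", sizes)])
        x = rng.normal(size=(len(labels), d))
        return ExpressionMatrix(
            x, [f"s{i}" for i in range(len(labels))], [f"f{j}" for j in range(d)], labels
        )

    _cfgs = dict(
        gcfg=GeneratorConfig(noise_dim=8, layer_widths=(16, 16, 1)),
        ccfg=CriticConfig(layer_widths=(1, 16, 16, 1)),
        tcfg=WGANTrainConfig(epochs=2, seed=0),
    )

    def test_balances_to_target_preserving_real_rows(self):
        em = self._em()
        out = augment_to_target(em, 40, **self._cfgs, seed=0)
        for cls in "abc":
            assert (out.labels == cls).sum() == 40
        np.testing.assert_array_equal(out.values[: em.n_samples], em.values)
        assert (out.provenance[: em.n_samples] == "real").all()
        n_synth = (out.provenance == "synthetic").sum()
        assert n_synth == (40 - 12) + (40 - 30) * 2

    def test_no_op_when_all_classes_at_target(self):
        em = self._em(sizes=(40, 40, 40))
        out = augment_to_target(em, 40, **self._cfgs, seed=0)
        np.testing.assert_array_equal(out.values, em.values)
        assert out.samples == em.samples

    def test_target_below_largest_class_passes_through_with_warning(self, caplog):
        em = self._em(sizes=(5, 30, 30))
        with caplog.at_level("WARNING"):
            out = augment_to_target(em, 20, **self._cfgs, seed=0)
        assert "pass through" in caplog.text
        assert (out.labels == "b").sum() == 30  # untouched
        assert (out.labels == "a").sum() == 20  # topped up

    def test_deterministic_given_seed_and_configs(self):
        em = self._em()
        out1 = augment_to_target(em, 40, **self._cfgs, seed=3)
        out2 = augment_to_target(em, 40, **self._cfgs, seed=3)
        np.testing.assert_array_equal(out1.values, out2.values)
        assert out1.samples == out2.samples
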