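"""Conditional VAE: KL closed form, reparameterization, encoder/decoder
contracts, and latent-space class structure after training."""

import numpy as np
import pytest

from dopplerauth import ConditionalVAE, kl_gaussians, train_cvae
from dopplerauth.cvae import CvaeConfig, reparameterize


def make_two_class_images(n_per_class=60, size=16, seed=0):
    """Two synthetic spectrogram populations with distinct frequency bands."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label, row in ((0, 3), (1, 10)):
        for _ in range(n_per_class):
            img = 0.08 * rng.random((size, size))
            img[row : row + 3, :] += 0.8 + 0.1 * rng.random((3, size))
            X.append(np.clip(img, 0, 1))
            y.append(label)
    return np.asarray(X, dtype=np.float32), np.asarray(y)


class TestKlGaussians:
    def test_identical_distributions_give_zero(self):
        mu = np.zeros((3, 4))
        lv = np.zeros((3, 4))
        assert np.allclose(kl_gaussians(mu, lv, mu, lv), 0.0)

    def test_unit_shift_gives_half(self):
        assert kl_gaussians([1.0], [0.0], [0.0], [0.0]) == pytest.approx(0.5)

    def test_matches_monte_carlo_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            d = int(rng.integers(1, 6))
            mu_q, mu_p = rng.normal(size=d), rng.normal(size=d)
            lv_q, lv_p = rng.uniform(-1, 1, d), rng.uniform(-1, 1, d)
            z = mu_q + rng.standard_normal((200_000, d)) * np.exp(0.5 * lv_q)

            def logpdf(x, mu, lv):
                return -0.5 * (((x - mu) ** 2) / np.exp(lv) + lv + np.log(2 * np.pi)).sum(axis=1)

            mc = np.mean(logpdf(z, mu_q, lv_q) - logpdf(z, mu_p, lv_p))
            closed = kl_gaussians(mu_q, lv_q, mu_p, lv_p)
            assert abs(mc - closed) / max(closed, 1e-3) < 0.01

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            kl_gaussians([0.0, 0.0], [0.0, 0.0], [0.0], [0.0])


class TestReparameterize:
    def test_zero_variance_limit_returns_mean(self):
        mu = np.array([1.5, -2.0])
        z = reparameterize(mu, np.full(2, -50.0), seed=0)
        assert np.allclose(z, mu, atol=1e-9)

    def test_sample_statistics(self):
        n = 100_000
        z = reparameterize(np.zeros(n), np.zeros(n), seed=1)
        assert abs(z.mean()) < 3 / np.sqrt(n)
        assert abs(z.var() - 1) < 3 * np.sqrt(2 / n)

    def test_seed_determinism(self):
        mu, lv = np.zeros(5), np.zeros(5)
        assert np.array_equal(reparameterize(mu, lv, 7), reparameterize(mu, lv, 7))


class TestUntrainedContracts:
    @pytest.fixture(scope="class")
    def built(self):
        m = ConditionalVAE(latent_dim=50, enc_channels=(2, 4, 8), random_state=0)
        m.build((16, 16), [0, 1])
        return m

    def test_encode_deterministic_and_label_free(self, built):
        x = np.random.default_rng(0).random((3, 16, 16)).astype(np.float32)
        a, b = built.encode(x), built.encode(x)
        assert np.array_equal(a.mean, b.mean)
        assert a.mean.shape == (3, 50)
        assert np.all(np.exp(a.log_variance) > 0)

    def test_batch_order_preserved(self, built):
        x = np.random.default_rng(1).random((4, 16, 16)).astype(np.float32)
        full = built.transform(x)
        for i in range(4):
            assert np.allclose(built.transform(x[i : i + 1])[0], full[i])

    def test_shape_mismatch_rejected(self, built):
        with pytest.raises(ValueError):
            built.encode(np.zeros((2, 8, 8)))

    def test_decode_contract(self, built):
        out = built.decode(np.zeros(50))
        assert out.shape == (1, 16, 16)
        assert np.all((out >= 0) & (out <= 1))
        with pytest.raises(ValueError):
            built.decode(np.zeros(10))

    def test_loss_additivity_and_kl_sign(self, built):
        x = np.random.default_rng(2).random((6, 16, 16)).astype(np.float32)
        y = np.array([0, 1, 0, 1, 0, 1])
        total, recon, kl = built.loss(x, y, seed=0)
        assert total == pytest.approx(recon + kl, rel=1e-6)
        assert kl >= 0
        with pytest.raises(ValueError):
            built.loss(x, np.array([0, 1, 0, 1, 0, 5]), seed=0)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self):
        X, y = make_two_class_images(n_per_class=100)
        m = ConditionalVAE(
            latent_dim=8, epochs=60, lr=3e-3, batch_size=64,
            enc_channels=(4, 8, 16), random_state=0,
        )
        m.fit(X, y)
        return m, X, y

    def test_loss_halves_from_start(self, trained):
        m, _, _ = trained
        assert m.history_[-1, 0] <= 0.5 * m.history_[0, 0]
        assert np.all(np.isfinite(m.history_))

    def test_latent_classes_separate(self, trained):
        m, X, y = trained
        Z = m.transform(X)
        c0, c1 = Z[y == 0].mean(axis=0), Z[y == 1].mean(axis=0)
        spread = 0.5 * (
            np.linalg.norm(Z[y == 0] - c0, axis=1).mean()
            + np.linalg.norm(Z[y == 1] - c1, axis=1).mean()
        )
        assert np.linalg.norm(c0 - c1) > spread

    def test_prior_means_reproduce_labels(self, trained):
        m, X, y = trained
        Z = m.transform(X)
        mu_p, _ = m.prior_params(np.array([0, 1]))
        d = np.linalg.norm(Z[:, None, :] - mu_p[None, :, :], axis=2)
        assert (d.argmin(axis=1) == y).mean() >= 0.9

    def test_reconstruction_beats_mean_image_baseline(self, trained):
        m, X, y = trained
        recon = m.decode(m.transform(X))
        mse = np.mean((recon - X) ** 2)
        baseline = np.mean((X.mean(axis=0) - X) ** 2)
        assert mse < 0.5 * baseline

    def test_seed_determinism(self, trained):
        m, X, y = trained
        m2 = ConditionalVAE(
            latent_dim=8, epochs=5, lr=1e-3, batch_size=64,
            enc_channels=(2, 4, 8), random_state=0,
        )
        m2.fit(X, y)
        m3 = ConditionalVAE(
            latent_dim=8, epochs=5, lr=1e-3, batch_size=64,
            enc_channels=(2, 4, 8), random_state=0,
        )
        m3.fit(X, y)
        assert np.array_equal(m2.history_, m3.history_)

    def test_missing_label_class_rejected(self):
        X, y = make_two_class_images(10)
        with pytest.raises(ValueError):
            train_cvae(X, np.zeros_like(y), CvaeConfig(n_labels=2, epochs=1), 0)

    def test_single_class_rejected(self):
        X, _ = make_two_class_images(5)
        with pytest.raises(ValueError):
            ConditionalVAE(epochs=1).fit(X, np.zeros(len(X)))
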