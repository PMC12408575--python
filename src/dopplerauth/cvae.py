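"""Conditional VAE with a label-conditioned Gaussian prior.

The model learns per-subject latent clusters from beat spectrograms x with
subject labels y in {0..K-1}:

* decoder      p_theta(x|z)   - sigmoid-bounded mean image mu_theta(z),
* prior        p_psi(z|y)     = N(mu_psi(y), sigma_psi^2(y)),
* posterior    q_phi(z|x)     = N(mu_phi(x), sigma_phi^2(x)).

Unlike the classic conditional VAE, the encoder sees no label: it must
extract subject-specific structure on its own, while the label-conditioned
prior pulls each subject's posteriors toward a subject-specific Gaussian.
Training maximizes the evidence lower bound; with the Gaussian families the
KL term is closed-form, and the reconstruction term is a pixel-summed MSE
against the [0,1] spectrogram (a Bernoulli cross-entropy alternative is
provided).  Samples use the reparameterization z = mu + eps (.) sigma.

Authentication downstream uses only the encoder means; the decoder exists to
shape the latent space during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from dopplerauth.nn import (
    Adam,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Flatten,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Sigmoid,
)

__all__ = [
    "CvaeConfig",
    "LatentPoint",
    "kl_gaussians",
    "reparameterize",
    "ConditionalVAE",
    "train_cvae",
]

_LOGVAR_CLIP = 10.0


@dataclass(frozen=True)
class CvaeConfig:
    """Hyperparameters: latent dimension 50, batch size 64, 300 epochs,
    Adam with learning rate 1e-5."""

    latent_dim: int = 50
    batch_size: int = 64
    epochs: int = 300
    lr: float = 1e-5
    input_shape: tuple[int, int] = (64, 64)
    n_labels: int = 2
    enc_channels: tuple[int, int, int] = (16, 32, 64)
    prior_hidden: int = 64
    beta: float = 1.0
    reconstruction: str = "mse"

    def __post_init__(self) -> None:
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.n_labels < 2:
            raise ValueError("need at least two labels")
        if self.reconstruction not in ("mse", "bernoulli"):
            raise ValueError("reconstruction must be 'mse' or 'bernoulli'")


@dataclass
class LatentPoint:
    """Encoder output for one spectrogram: mean, log-variance, and sample."""

    mean: np.ndarray
    log_variance: np.ndarray
    sample: np.ndarray | None = None


def kl_gaussians(
    mean_q: np.ndarray,
    logvar_q: np.ndarray,
    mean_p: np.ndarray,
    logvar_p: np.ndarray,
) -> np.ndarray:
    """Closed-form KL(N_q || N_p) for diagonal Gaussians, per item.

    KL = sum_d [ 0.5*(logvar_p - logvar_q)
                 + (var_q + (mu_q - mu_p)^2) / (2 var_p) - 0.5 ].
    """
    mean_q, logvar_q, mean_p, logvar_p = (
        np.asarray(a, dtype=np.float64) for a in (mean_q, logvar_q, mean_p, logvar_p)
    )
    if mean_q.shape != mean_p.shape:
        raise ValueError("dimension mismatch between posterior and prior")
    var_q, var_p = np.exp(logvar_q), np.exp(logvar_p)
    if np.any(var_q <= 0) or np.any(var_p <= 0):
        raise ValueError("variances must be strictly positive")
    term = 0.5 * (logvar_p - logvar_q) + (var_q + (mean_q - mean_p) ** 2) / (2 * var_p) - 0.5
    return term.sum(axis=-1)


def reparameterize(
    mean: np.ndarray, log_variance: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """z = mu + eps (.) sigma with eps ~ N(0, I), sigma = exp(logvar / 2)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(np.shape(mean))
    return np.asarray(mean) + eps * np.exp(0.5 * np.asarray(log_variance))


class _Encoder(Module):
    """Conv (3x3) + ReLU + 2x2 max-pool stack, then FFN to (mu, logvar)."""

    def __init__(self, cfg: CvaeConfig, rng, dtype=np.float32):
        c1, c2, c3 = cfg.enc_channels
        h, w = cfg.input_shape
        if h % 8 or w % 8:
            raise ValueError("input_shape must be divisible by 8")
        self.stack = Sequential(
            Conv2d(1, c1, 3, rng, dtype), ReLU(), MaxPool2d(),
            Conv2d(c1, c2, 3, rng, dtype), ReLU(), MaxPool2d(),
            Conv2d(c2, c3, 3, rng, dtype), ReLU(), MaxPool2d(),
            Flatten(),
        )
        # small head init keeps initial posteriors near N(0, 1)
        self.head = Dense(c3 * (h // 8) * (w // 8), 2 * cfg.latent_dim, rng, dtype,
                          weight_scale=0.01)
        self.latent_dim = cfg.latent_dim

    def forward(self, x):
        out = self.head(self.stack(x[:, None, :, :]))
        return out[:, : self.latent_dim], out[:, self.latent_dim:]

    def backward(self, g_mean, g_logvar):
        g = np.concatenate([g_mean, g_logvar], axis=1)
        return self.stack.backward(self.head.backward(g))


class _Decoder(Module):
    """FFN from z, then transposed-conv stack to a sigmoid mean image."""

    def __init__(self, cfg: CvaeConfig, rng, dtype=np.float32):
        c1, c2, c3 = cfg.enc_channels
        h, w = cfg.input_shape
        self._c3, self._h8, self._w8 = c3, h // 8, w // 8
        self.fc = Dense(cfg.latent_dim, c3 * (h // 8) * (w // 8), rng, dtype)
        self.relu = ReLU()
        self.stack = Sequential(
            ConvTranspose2d(c3, c2, rng, dtype), ReLU(),
            ConvTranspose2d(c2, c1, rng, dtype), ReLU(),
            ConvTranspose2d(c1, 1, rng, dtype),
        )
        self.sig = Sigmoid()

    def forward(self, z):
        h = self.relu(self.fc(z))
        h = h.reshape(h.shape[0], self._c3, self._h8, self._w8)
        return self.sig(self.stack(h))[:, 0, :, :]

    def backward(self, g):
        g = self.stack.backward(self.sig.backward(g[:, None, :, :]))
        g = self.relu.backward(g.reshape(g.shape[0], -1))
        return self.fc.backward(g)


class _PriorNet(Module):
    """FFN mapping a one-hot label to latent prior parameters (mu, logvar)."""

    def __init__(self, cfg: CvaeConfig, rng, dtype=np.float32):
        self.fc1 = Dense(cfg.n_labels, cfg.prior_hidden, rng, dtype)
        self.relu = ReLU()
        self.fc2 = Dense(cfg.prior_hidden, 2 * cfg.latent_dim, rng, dtype,
                         weight_scale=0.01)
        self.latent_dim = cfg.latent_dim

    def forward(self, onehot):
        out = self.fc2(self.relu(self.fc1(onehot)))
        return out[:, : self.latent_dim], out[:, self.latent_dim:]

    def backward(self, g_mean, g_logvar):
        g = np.concatenate([g_mean, g_logvar], axis=1)
        return self.fc1.backward(self.relu.backward(self.fc2.backward(g)))


def _clip_logvar(lv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = (np.abs(lv) < _LOGVAR_CLIP).astype(lv.dtype)
    return np.clip(lv, -_LOGVAR_CLIP, _LOGVAR_CLIP), mask


class ConditionalVAE(BaseEstimator, TransformerMixin):
    """Conditional VAE estimator (scikit-learn protocol).

    ``fit(X, y)`` trains encoder/decoder/prior on spectrograms
    ``X`` of shape (n, n_freq, n_time) with values in [0, 1] and integer
    labels ``y``; ``transform(X)`` returns encoder means, the latent
    features all downstream authentication uses.

    The per-item loss is the negative evidence lower bound

        sum_pixels (x - mu_theta(z))^2 + beta * KL(q_phi(z|x) || p_psi(z|y))

    with z drawn once per item via the reparameterization trick; the batch
    loss is the item mean.  ``history_`` records per-epoch
    (total, reconstruction, KL) means.
    """

    def __init__(
        self,
        latent_dim: int = 50,
        batch_size: int = 64,
        epochs: int = 300,
        lr: float = 1e-5,
        enc_channels: tuple[int, int, int] = (16, 32, 64),
        prior_hidden: int = 64,
        beta: float = 1.0,
        reconstruction: str = "mse",
        random_state: int | None = 0,
    ):
        self.latent_dim = latent_dim
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr = lr
        self.enc_channels = enc_channels
        self.prior_hidden = prior_hidden
        self.beta = beta
        self.reconstruction = reconstruction
        self.random_state = random_state

    # -- pieces -----------------------------------------------------------

    def _onehot(self, y: np.ndarray) -> np.ndarray:
        oh = np.zeros((len(y), len(self.classes_)), dtype=np.float32)
        oh[np.arange(len(y)), y] = 1.0
        return oh

    def _label_index(self, y) -> np.ndarray:
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        bad = (idx >= len(self.classes_)) | (self.classes_[np.minimum(idx, len(self.classes_) - 1)] != y)
        if np.any(bad):
            raise ValueError(f"labels {np.unique(y[bad])} not in training classes")
        return idx

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3 or X.shape[1:] != self.input_shape_:
            raise ValueError(f"expected spectrograms of shape {self.input_shape_}")
        return X

    # -- training ---------------------------------------------------------

    def _batch_loss(self, xb, yb_idx, rng, train=True):
        enc, dec, prior = self.encoder_, self.decoder_, self.prior_
        bsz = xb.shape[0]
        mu_q, lv_q_raw = enc.forward(xb)
        lv_q, mask_q = _clip_logvar(lv_q_raw)
        mu_p, lv_p_raw = prior.forward(self._onehot(yb_idx))
        lv_p, mask_p = _clip_logvar(lv_p_raw)

        eps = rng.standard_normal(mu_q.shape).astype(np.float32)
        sd_q = np.exp(0.5 * lv_q)
        z = mu_q + eps * sd_q
        xhat = dec.forward(z)

        if self.reconstruction == "bernoulli":
            xc = np.clip(xhat, 1e-6, 1.0 - 1e-6)
            recon_i = -(xb * np.log(xc) + (1 - xb) * np.log(1 - xc)).sum(axis=(1, 2))
            g_xhat_unit = (xc - xb) / (xc * (1 - xc))
        else:
            err = xhat - xb
            recon_i = (err ** 2).sum(axis=(1, 2))
            g_xhat_unit = 2.0 * err
        var_q, var_p = np.exp(lv_q), np.exp(lv_p)
        dmu = mu_q - mu_p
        kl_i = (0.5 * (lv_p - lv_q) + (var_q + dmu ** 2) / (2 * var_p) - 0.5).sum(axis=1)
        recon = float(recon_i.mean())
        kl = float(kl_i.mean())
        total = recon + self.beta * kl
        if not train:
            return total, recon, kl

        # gradients of the mean-over-batch loss
        g_xhat = g_xhat_unit / bsz
        g_z = dec.backward(g_xhat)
        g_mu_q = g_z.copy()
        g_lv_q = g_z * eps * 0.5 * sd_q

        scale = self.beta / bsz
        g_mu_q += scale * (dmu / var_p)
        g_lv_q += scale * 0.5 * (var_q / var_p - 1.0)
        g_mu_p = -scale * (dmu / var_p)
        g_lv_p = scale * 0.5 * (1.0 - (var_q + dmu ** 2) / var_p)

        enc.backward(g_mu_q.astype(np.float32), (g_lv_q * mask_q).astype(np.float32))
        prior.backward(g_mu_p.astype(np.float32), (g_lv_p * mask_p).astype(np.float32))
        return total, recon, kl

    def build(self, input_shape: tuple[int, int], classes) -> "ConditionalVAE":
        """Construct (untrained) networks for a given input shape and label
        vocabulary; used by fit and by checkpoint loading."""
        self.classes_ = np.asarray(classes)
        self.input_shape_ = tuple(input_shape)
        cfg = CvaeConfig(
            latent_dim=self.latent_dim,
            batch_size=self.batch_size,
            epochs=self.epochs,
            lr=self.lr,
            input_shape=self.input_shape_,
            n_labels=len(self.classes_),
            enc_channels=tuple(self.enc_channels),
            prior_hidden=self.prior_hidden,
            beta=self.beta,
            reconstruction=self.reconstruction,
        )
        self._cfg = cfg
        rng = np.random.default_rng(self.random_state)
        self.encoder_ = _Encoder(cfg, rng)
        self.decoder_ = _Decoder(cfg, rng)
        self.prior_ = _PriorNet(cfg, rng)
        self._train_rng = rng  # continues the same stream for shuffling/noise
        return self

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ConditionalVAE":
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("X must be a non-empty (n, n_freq, n_time) array")
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two label classes")
        self.build(X.shape[1:], classes)
        cfg = self._cfg
        rng = self._train_rng
        params = (
            self.encoder_.parameters()
            + self.decoder_.parameters()
            + self.prior_.parameters()
        )
        opt = Adam(params, lr=cfg.lr)
        y_idx = self._label_index(y)
        n = len(X)
        bs = min(cfg.batch_size, n)
        history = []
        for _ in range(cfg.epochs):
            perm = rng.permutation(n)
            tot, rec, kl, nb = 0.0, 0.0, 0.0, 0
            for s in range(0, n, bs):
                idx = perm[s : s + bs]
                for p in params:
                    p.grad[...] = 0.0
                t, r, k = self._batch_loss(X[idx], y_idx[idx], rng, train=True)
                if not np.isfinite(t):
                    raise FloatingPointError("non-finite training loss")
                opt.step()
                tot += t; rec += r; kl += k; nb += 1
            history.append((tot / nb, rec / nb, kl / nb))
        self.history_ = np.asarray(history)
        return self

    # -- inference --------------------------------------------------------

    def encode(self, X: np.ndarray) -> LatentPoint:
        """Posterior parameters mu_phi(x), log sigma_phi^2(x); label-free."""
        if not hasattr(self, "encoder_"):
            raise RuntimeError("model is not fitted")
        X = self._check_input(X)
        mu, lv_raw = self.encoder_.forward(X)
        lv, _ = _clip_logvar(lv_raw)
        return LatentPoint(mean=np.asarray(mu, dtype=np.float64),
                           log_variance=np.asarray(lv, dtype=np.float64))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Latent features = encoder means."""
        return self.encode(X).mean

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Reconstructed spectrogram mean in [0, 1] for latent z."""
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 1:
            z = z[None]
        if z.shape[1] != self.latent_dim:
            raise ValueError(f"z must have dimension {self.latent_dim}")
        return np.asarray(self.decoder_.forward(z), dtype=np.float64)

    def prior_params(self, y) -> tuple[np.ndarray, np.ndarray]:
        """Label-conditioned prior (mu_psi(y), log sigma_psi^2(y))."""
        idx = self._label_index(np.atleast_1d(y))
        mu, lv_raw = self.prior_.forward(self._onehot(idx))
        lv, _ = _clip_logvar(lv_raw)
        return np.asarray(mu, dtype=np.float64), np.asarray(lv, dtype=np.float64)

    def loss(self, X: np.ndarray, y, seed: int = 0) -> tuple[float, float, float]:
        """(total, reconstruction, KL) means over a batch; labels must be known."""
        X = self._check_input(X)
        idx = self._label_index(np.asarray(y))
        rng = np.random.default_rng(seed)
        return self._batch_loss(X, idx, rng, train=False)


def train_cvae(
    X: np.ndarray,
    y: np.ndarray,
    config: CvaeConfig | None = None,
    seed: int = 0,
) -> tuple[ConditionalVAE, np.ndarray]:
    """Functional wrapper: train a conditional VAE, return (model, history).

    Verifies every label in ``range(n_labels)`` is represented before
    training when a config with ``n_labels`` is given.
    """
    cfg = config or CvaeConfig()
    present = set(np.unique(y).tolist())
    missing = set(range(cfg.n_labels)) - present
    if missing:
        raise ValueError(f"label classes missing from training data: {sorted(missing)}")
    model = ConditionalVAE(
        latent_dim=cfg.latent_dim,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        lr=cfg.lr,
        enc_channels=cfg.enc_channels,
        prior_hidden=cfg.prior_hidden,
        beta=cfg.beta,
        reconstruction=cfg.reconstruction,
        random_state=seed,
    )
    model.fit(X, y)
    return model, model.history_
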