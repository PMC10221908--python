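"""Variational autoencoder over encoded motion images, with KPMSE.

The tour duplicates some joints across several columns, so a faithful
generated image must keep those columns equal.  KPMSE (key-point mean
squared error) penalizes disagreement within each duplicate group:

    KPMSE = sum over rows, duplicate groups, unordered column pairs (i, j)
            of (x_i - x_j)^2 + (y_i - y_j)^2 + (c_i - c_j)^2

and the training loss is  MSE + beta * DKL + alpha * KPMSE  with
alpha, beta in [0, 1].  DKL is the closed-form KL divergence between the
encoder's diagonal Gaussian and N(0, I).  So that alpha and beta weigh
comparable magnitudes, the loss uses per-element means: MSE is the mean
over pixels, DKL is divided by the flattened input dimension, and the
KPMSE term is divided by (rows x pairs x 3); the public :func:`kpmse`
returns the raw sum.

The network is a compact fully connected encoder/decoder pair sized for
49x49x3 input with hand-written backpropagation; the architecture is a
contract, not a mandate — any backbone exposing ``encode``/``decode``
with the same signatures can replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .codec import TSSCIImage
from .errors import CannotFitError
from .skeleton import TourOrder, body25_tour


@dataclass
class VAEConfig:
    """Training configuration; alpha weighs KPMSE, beta weighs DKL."""

    latent_dim: int = 16
    alpha: float = 0.5
    beta: float = 0.5
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    hidden_dims: tuple[int, ...] = (256, 256)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")


def _duplicate_groups(tour: TourOrder) -> list[np.ndarray]:
    """Column index arrays of the joints that appear more than once."""
    return [
        np.asarray(positions)
        for positions in tour.duplicate_groups.values()
        if len(positions) > 1
    ]


def _n_pairs(tour: TourOrder) -> int:
    return sum(len(g) * (len(g) - 1) // 2 for g in _duplicate_groups(tour))


def _as_pixel_array(image) -> np.ndarray:
    return image.pixels if isinstance(image, TSSCIImage) else np.asarray(image, dtype=float)


def kpmse(image, tour: TourOrder | None = None) -> float:
    """Raw duplicate-column disagreement of one image (sum over all pairs).

    Uses the identity sum_{i<j}(x_i - x_j)^2 = d * sum(x^2) - (sum x)^2
    per row, channel and duplicate group.  Zero iff every duplicate
    group's columns are identical.
    """
    pixels = _as_pixel_array(image)
    tour = tour or body25_tour()
    total = 0.0
    for cols in _duplicate_groups(tour):
        sub = pixels[:, cols, :]  # (rows, d, 3)
        d = len(cols)
        total += float((d * (sub**2).sum(axis=1) - sub.sum(axis=1) ** 2).sum())
    return total


def _kpmse_batch(batch: np.ndarray, groups: Sequence[np.ndarray]) -> tuple[float, np.ndarray]:
    """Summed KPMSE over a (B, rows, cols, 3) batch and its gradient."""
    total = 0.0
    grad = np.zeros_like(batch)
    for cols in groups:
        sub = batch[:, :, cols, :]
        d = len(cols)
        s = sub.sum(axis=2, keepdims=True)
        total += float((d * (sub**2).sum(axis=2) - (s[:, :, 0, :]) ** 2).sum())
        grad[:, :, cols, :] += 2.0 * (d * sub - s)
    return total, grad


def gaussian_kl(mu: np.ndarray, logvar: np.ndarray) -> np.ndarray:
    """Per-sample KL( N(mu, diag(exp(logvar))) || N(0, I) )."""
    return -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=-1)


def vae_loss(
    recon,
    target,
    mu: np.ndarray,
    logvar: np.ndarray,
    config: VAEConfig,
    tour: TourOrder | None = None,
) -> tuple[float, float, float, float]:
    """(total, mse, dkl, kpmse) loss components for a batch of images.

    With ``alpha = 0`` the total reduces to the plain VAE objective
    MSE + beta * DKL.  All terms are per-element means (see module note).
    """
    tour = tour or body25_tour()
    recon = np.atleast_3d(_as_pixel_array(recon))
    target = np.atleast_3d(_as_pixel_array(target))
    if recon.ndim == 3:
        recon = recon[None]
        target = target[None]
    mu = np.atleast_2d(mu)
    logvar = np.atleast_2d(logvar)
    batch, n_elems = recon.shape[0], recon[0].size
    mse = float(np.mean((recon - target) ** 2))
    dkl = float(np.mean(gaussian_kl(mu, logvar))) / n_elems
    groups = _duplicate_groups(tour)
    kp_raw, _ = _kpmse_batch(recon, groups)
    denom = batch * recon.shape[1] * max(_n_pairs(tour), 1) * 3
    kp = kp_raw / denom
    total = mse + config.beta * dkl + config.alpha * kp
    return total, mse, dkl, kp


class _Adam:
    """Minimal Adam optimizer over a dict of named arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class VAE:
    """Fully connected VAE: D -> hidden -> latent -> hidden -> D.

    ``encode`` maps images to (mu, logvar); ``decode`` maps latent
    vectors to images with pixels in [0, 1].  Training history (one dict
    of mean loss components per epoch) is kept in ``history``.
    """

    config: VAEConfig = field(default_factory=VAEConfig)
    tour: TourOrder = field(default_factory=body25_tour)
    input_shape: tuple[int, int, int] = (49, 49, 3)
    params: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    history: list[dict[str, float]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.params:
            self._init_params()
        self._groups = _duplicate_groups(self.tour)
        self._pairs = max(_n_pairs(self.tour), 1)

    @property
    def input_dim(self) -> int:
        return int(np.prod(self.input_shape))

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        d, latent = self.input_dim, self.config.latent_dim
        hidden = tuple(self.config.hidden_dims)

        def init(n_in: int, n_out: int, scale: float = 1.0) -> np.ndarray:
            return rng.normal(0.0, scale * np.sqrt(2.0 / n_in), size=(n_in, n_out))

        params: dict[str, np.ndarray] = {}
        n_in = d
        for i, h in enumerate(hidden):  # encoder stack
            params[f"eW{i}"], params[f"eb{i}"] = init(n_in, h), np.zeros(h)
            n_in = h
        params["Wm"], params["bm"] = init(n_in, latent, 0.1), np.zeros(latent)
        params["Wv"], params["bv"] = init(n_in, latent, 0.1), np.zeros(latent)
        n_in = latent
        for i, h in enumerate(reversed(hidden)):  # decoder stack
            params[f"dW{i}"], params[f"db{i}"] = init(n_in, h), np.zeros(h)
            n_in = h
        params["Wo"], params["bo"] = init(n_in, d, 0.1), np.zeros(d)
        self.params = params

    @property
    def _depth(self) -> int:
        return len(self.config.hidden_dims)

    def _encoder_stack(self, x: np.ndarray) -> list[np.ndarray]:
        acts = [x]
        for i in range(self._depth):
            acts.append(_relu(acts[-1] @ self.params[f"eW{i}"] + self.params[f"eb{i}"]))
        return acts

    def _decoder_stack(self, z: np.ndarray) -> list[np.ndarray]:
        acts = [z]
        for i in range(self._depth):
            acts.append(_relu(acts[-1] @ self.params[f"dW{i}"] + self.params[f"db{i}"]))
        return acts

    # -- contract surface ---------------------------------------------------

    def encode(self, images) -> tuple[np.ndarray, np.ndarray]:
        """Images (N, rows, cols, 3) or a single image -> (mu, logvar)."""
        x, single = self._flatten(images)
        h = self._encoder_stack(x)[-1]
        mu = h @ self.params["Wm"] + self.params["bm"]
        logvar = np.clip(h @ self.params["Wv"] + self.params["bv"], -8.0, 8.0)
        if single:
            return mu[0], logvar[0]
        return mu, logvar

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Latent vectors (N, latent) or (latent,) -> images in [0, 1]."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        z2 = z[None] if single else z
        h = self._decoder_stack(z2)[-1]
        y = _sigmoid(h @ self.params["Wo"] + self.params["bo"])
        images = np.clip(y, 0.0, 1.0).reshape(-1, *self.input_shape)
        return images[0] if single else images

    def reconstruct(self, images) -> np.ndarray:
        """Deterministic round trip through the latent mean."""
        mu, _ = self.encode(images)
        return self.decode(mu)

    def sample(self, n: int, seed: int = 0) -> np.ndarray:
        """Decode n draws from the standard normal prior."""
        rng = np.random.default_rng(seed)
        return self.decode(rng.standard_normal((n, self.config.latent_dim)))

    # -- training -----------------------------------------------------------

    def _flatten(self, images) -> tuple[np.ndarray, bool]:
        if isinstance(images, TSSCIImage):
            return images.pixels.reshape(1, -1), True
        arr = np.asarray(
            [_as_pixel_array(im) for im in images]
            if isinstance(images, (list, tuple))
            else images,
            dtype=float,
        )
        if arr.ndim == 3:
            return arr.reshape(1, -1), True
        return arr.reshape(arr.shape[0], -1), False

    def fit(self, images, verbose: bool = False) -> "VAE":
        x_all, _ = self._flatten(images)
        n = x_all.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        opt = _Adam(self.params, cfg.learning_rate)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            sums = {"total": 0.0, "mse": 0.0, "dkl": 0.0, "kpmse": 0.0}
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                batch = x_all[order[start : start + cfg.batch_size]]
                losses = self._train_step(batch, rng, opt)
                for k, v in zip(sums, losses):
                    sums[k] += v
                n_batches += 1
            self.history.append({k: v / n_batches for k, v in sums.items()})
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}: " + ", ".join(
                    f"{k}={v:.5f}" for k, v in self.history[-1].items()))
        return self

    def _train_step(self, x, rng, opt) -> tuple[float, float, float, float]:
        p, cfg = self.params, self.config
        batch, d = x.shape
        rows = self.input_shape[0]
        depth = self._depth

        enc = self._encoder_stack(x)
        h_enc = enc[-1]
        mu = h_enc @ p["Wm"] + p["bm"]
        logvar = np.clip(h_enc @ p["Wv"] + p["bv"], -8.0, 8.0)
        eps = rng.standard_normal(mu.shape)
        std = np.exp(0.5 * logvar)
        z = mu + eps * std
        dec = self._decoder_stack(z)
        h_dec = dec[-1]
        y = _sigmoid(h_dec @ p["Wo"] + p["bo"])

        diff = y - x
        mse = float(np.mean(diff**2))
        dkl = float(np.mean(gaussian_kl(mu, logvar))) / d
        y_img = y.reshape(batch, *self.input_shape)
        kp_raw, kp_grad_img = _kpmse_batch(y_img, self._groups)
        kp_denom = batch * rows * self._pairs * 3
        kp = kp_raw / kp_denom
        total = mse + cfg.beta * dkl + cfg.alpha * kp

        dy = 2.0 * diff / (batch * d) + cfg.alpha * kp_grad_img.reshape(batch, d) / kp_denom
        dlogits = dy * y * (1.0 - y)
        grads = {"Wo": h_dec.T @ dlogits, "bo": dlogits.sum(axis=0)}
        dh = dlogits @ p["Wo"].T
        for i in range(depth - 1, -1, -1):  # back through decoder stack
            dh_pre = dh * (dec[i + 1] > 0)
            grads[f"dW{i}"] = dec[i].T @ dh_pre
            grads[f"db{i}"] = dh_pre.sum(axis=0)
            dh = dh_pre @ p[f"dW{i}"].T
        dz = dh

        kl_scale = cfg.beta / (batch * d)
        dmu = dz + kl_scale * mu
        dlogvar = dz * eps * 0.5 * std + kl_scale * 0.5 * (np.exp(logvar) - 1.0)
        grads["Wm"] = h_enc.T @ dmu
        grads["bm"] = dmu.sum(axis=0)
        grads["Wv"] = h_enc.T @ dlogvar
        grads["bv"] = dlogvar.sum(axis=0)
        dh = dmu @ p["Wm"].T + dlogvar @ p["Wv"].T
        for i in range(depth - 1, -1, -1):  # back through encoder stack
            dh_pre = dh * (enc[i + 1] > 0)
            grads[f"eW{i}"] = enc[i].T @ dh_pre
            grads[f"eb{i}"] = dh_pre.sum(axis=0)
            dh = dh_pre @ p[f"eW{i}"].T

        opt.step(p, grads)
        return total, mse, dkl, kp

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = np.array(
            [self.config.latent_dim, self.config.alpha, self.config.beta,
             self.config.seed]
        )
        np.savez_compressed(
            Path(path), meta=meta, shape=np.array(self.input_shape),
            hidden=np.array(self.config.hidden_dims), **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "VAE":
        archive = np.load(Path(path))
        meta = archive["meta"]
        config = VAEConfig(
            latent_dim=int(meta[0]), alpha=float(meta[1]), beta=float(meta[2]),
            seed=int(meta[3]), hidden_dims=tuple(int(h) for h in archive["hidden"]),
        )
        params = {
            k: archive[k] for k in archive.files if k not in ("meta", "shape", "hidden")
        }
        return cls(config=config, input_shape=tuple(archive["shape"]), params=params)


def train_vae(
    dataset: Sequence, config: VAEConfig | None = None, tour: TourOrder | None = None,
    verbose: bool = False,
) -> VAE:
    """Train a VAE on encoded images; returns the fitted encoder/decoder."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or VAEConfig()
    shape = _as_pixel_array(dataset[0]).shape
    vae = VAE(config=config, tour=tour or body25_tour(), input_shape=shape)
    return vae.fit(dataset, verbose=verbose)


def merge_latents(z1: np.ndarray, z2: np.ndarray) -> np.ndarray:
    """Elementwise mean of two latent vectors: the merged movement."""
    z1, z2 = np.asarray(z1, dtype=float), np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise ValueError(f"latent dims differ: {z1.shape} vs {z2.shape}")
    return (z1 + z2) / 2.0


def sample_class_conditional(
    latents: Sequence[np.ndarray], n: int, seed: int = 0
) -> np.ndarray:
    """Draw n latent vectors from the Gaussian fitted to one class's cloud.

    Each class occupies a sub-distribution of the latent space with its
    own per-dimension mean and variance; sampling from it and decoding
    yields new movements of that class.
    """
    cloud = np.asarray(latents, dtype=float)
    if cloud.ndim != 2 or cloud.shape[0] < 2:
        raise CannotFitError("need at least two class latents to fit a distribution")
    mean = cloud.mean(axis=0)
    std = cloud.std(axis=0)
    rng = np.random.default_rng(seed)
    return mean[None, :] + std[None, :] * rng.standard_normal((n, cloud.shape[1]))


def latent_tsne(latents: np.ndarray, seed: int = 0, perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE map of latent vectors (visualization helper)."""
    from sklearn.manifold import TSNE

    return TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(np.asarray(latents, dtype=float))
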