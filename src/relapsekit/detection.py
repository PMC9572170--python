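"""Training loops and anomaly-score probes for the autoencoders.

The detection recipe is train-on-normal: an autoencoder learns to
reconstruct normal data; per-point mean-absolute-error vectors e(i) from a
held-out normal subset (val2) parameterize a multivariate Gaussian
(mu, Sigma), and test instances are scored with the squared Mahalanobis
distance

    a(i) = (e(i) - mu)^T Sigma^{-1} (e(i) - mu).

Variational models additionally expose the KL divergence of the projected
latent distribution from N(0, I) as a probe, and a model-free baseline
applies the same Mahalanobis scoring to the raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .models import build_model
from .nn import Module, Tensor, make_optimizer

__all__ = [
    "TrainSpec",
    "TrainingDiverged",
    "ErrorDistribution",
    "train",
    "reconstruct",
    "error_vectors",
    "fit_error_distribution",
    "mahalanobis",
    "anomaly_score",
    "kl_score",
    "recon_score",
    "random_baseline",
]

_VARIATIONAL = ("cvae", "cvae1d")


@dataclass(frozen=True)
class TrainSpec:
    """Optimization protocol for one architecture.

    Defaults follow the reference recipes: physiological sequence models use
    batch 64, 50 epochs, lr 1e-4 (transformer 1e-3), Adam for fnn and
    transformer, RMSprop for cnn and gru; audio models use Adam with lr
    3e-4, batch 8, up to 200 epochs with early-stopping patience 10, and
    variational loss weights W_MSE = 1, W_KL = 0.01.
    """

    architecture: str
    optimizer: str = "adam"
    lr: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 5
    w_mse: float = 1.0
    w_kl: float = 0.01
    seed: int = 0

    @staticmethod
    def for_architecture(architecture: str, seed: int = 0) -> "TrainSpec":
        base = dict(architecture=architecture, seed=seed)
        if architecture == "fnn":
            return TrainSpec(**base, optimizer="adam", lr=1e-4)
        if architecture == "transformer":
            return TrainSpec(**base, optimizer="adam", lr=1e-3)
        if architecture in ("cnn", "gru"):
            return TrainSpec(**base, optimizer="rmsprop", lr=1e-4)
        if architecture in ("cae", "cvae", "cvae1d"):
            return TrainSpec(**base, optimizer="adam", lr=3e-4, batch_size=8,
                             max_epochs=200, patience=10)
        raise ValueError(f"unknown architecture {architecture!r}")


class TrainingDiverged(RuntimeError):
    pass


def _forward_loss(model: Module, batch: np.ndarray, spec: TrainSpec):
    x = Tensor(batch)
    if spec.architecture in _VARIATIONAL:
        recon, mu, logvar = model(x)
        diff = recon - x
        mse = (diff * diff).mean()
        kl = model.kl(mu, logvar).mean()
        return spec.w_mse * mse + spec.w_kl * kl
    recon = model(x)
    diff = recon - x
    return (diff * diff).mean()


def _dataset_loss(model: Module, data: np.ndarray, spec: TrainSpec) -> float:
    if len(data) == 0:
        return float("nan")
    model.eval()
    total = 0.0
    for lo in range(0, len(data), spec.batch_size):
        batch = data[lo : lo + spec.batch_size]
        total += float(_forward_loss(model, batch, spec).data) * len(batch)
    model.train()
    return total / len(data)


def train(model: Module, train_data: np.ndarray, val1_data: np.ndarray,
          spec: TrainSpec):
    """Minibatch training with early stopping on the first validation subset.

    Returns ``(model, history)`` with the best-val1 weights restored;
    ``history`` has per-epoch train and val1 losses. A zero-epoch budget
    returns the initialized model with an empty history.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(7,)))
    optimizer = make_optimizer(spec.optimizer, model.parameters(), spec.lr)
    history = {"train": [], "val1": []}
    best_val = float("inf")
    best_state = model.state()
    stale = 0
    model.train()
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(train_data))
        epoch_loss = 0.0
        for lo in range(0, len(order), spec.batch_size):
            batch = train_data[order[lo : lo + spec.batch_size]]
            model.zero_grad()
            loss = _forward_loss(model, batch, spec)
            value = float(loss.data)
            if not np.isfinite(value):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} ({spec.architecture}, "
                    f"lr={spec.lr}, batch={len(batch)})"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += value * len(batch)
        history["train"].append(epoch_loss / len(train_data))
        val_loss = _dataset_loss(model, val1_data, spec)
        history["val1"].append(val_loss)
        if np.isfinite(val_loss) and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state()
            stale = 0
        else:
            stale += 1
            if stale > spec.patience:
                break
    model.load_state(best_state)
    model.eval()
    return model, history


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def reconstruct(model: Module, data: np.ndarray, spec: TrainSpec,
                batch_size: int = 64) -> np.ndarray:
    model.eval()
    outs = []
    for lo in range(0, len(data), batch_size):
        x = Tensor(data[lo : lo + batch_size])
        out = model(x)
        if spec.architecture in _VARIATIONAL:
            out = out[0]
        outs.append(out.data)
    return np.concatenate(outs, axis=0)


def error_vectors(model: Module, data: np.ndarray, spec: TrainSpec) -> np.ndarray:
    """Per-point MAE error vectors.

    Sequence models (N, T, F) yield one F-dimensional error vector per time
    point, flattened to (N*T, F); spectrogram models (N, 1, H, W) yield one
    H-dimensional per-band MAE vector per slice; hourly tensors (N, T, F)
    are treated like sequences.
    """
    recon = reconstruct(model, data, spec)
    err = np.abs(recon - data)
    if err.ndim == 3:                     # (N, T, F) -> per time point
        return err.reshape(-1, err.shape[-1])
    if err.ndim == 4:                     # (N, 1, H, W) -> per-band MAE per slice
        return err.mean(axis=(1, 3))
    raise ValueError(f"unsupported data rank {err.ndim}")


@dataclass
class ErrorDistribution:
    mu: np.ndarray
    sigma: np.ndarray                      # ridge-regularized covariance
    ridge: float
    _inv: np.ndarray = field(default=None, repr=False)

    @property
    def inv(self) -> np.ndarray:
        if self._inv is None:
            self._inv = np.linalg.inv(self.sigma)
        return self._inv


def fit_error_distribution(errors: np.ndarray,
                           ridge_scale: float = 1e-6) -> ErrorDistribution:
    """Sample mean and covariance of error vectors with a scaled-trace ridge.

    The ridge epsilon = ridge_scale * trace(Sigma)/d keeps Sigma positive
    definite even with fewer points than dimensions.
    """
    e = np.atleast_2d(np.asarray(errors, dtype=float))
    if len(e) == 0:
        raise ValueError("empty validation error set")
    mu = e.mean(axis=0)
    d = e.shape[1]
    if len(e) > 1:
        sigma = np.cov(e, rowvar=False).reshape(d, d)
    else:
        sigma = np.zeros((d, d))
    eps = ridge_scale * (np.trace(sigma) / d if np.trace(sigma) > 0 else 1.0)
    sigma = sigma + eps * np.eye(d)
    return ErrorDistribution(mu=mu, sigma=sigma, ridge=eps)


def mahalanobis(vectors: np.ndarray, dist: ErrorDistribution) -> np.ndarray:
    """Squared Mahalanobis distance of each row from the fitted Gaussian."""
    diff = np.atleast_2d(vectors) - dist.mu
    return np.einsum("ij,jk,ik->i", diff, dist.inv, diff)


def anomaly_score(model: Module, dist: ErrorDistribution, data: np.ndarray,
                  spec: TrainSpec) -> np.ndarray:
    """Per-point (sequence) or per-slice (spectrogram) anomaly scores."""
    return mahalanobis(error_vectors(model, data, spec), dist)


def recon_score(model: Module, data: np.ndarray, spec: TrainSpec) -> np.ndarray:
    """Per-instance mean squared reconstruction error."""
    recon = reconstruct(model, data, spec)
    err = (recon - data) ** 2
    return err.reshape(len(data), -1).mean(axis=1)


def kl_score(model: Module, data: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """KL divergence of the projected latent distribution from N(0, I)."""
    if not hasattr(model, "kl"):
        raise TypeError("KL probe requires a variational model")
    model.eval()
    outs = []
    for lo in range(0, len(data), batch_size):
        mu, logvar = model.encode(Tensor(data[lo : lo + batch_size]))
        outs.append(model.kl(mu, logvar).data)
    return np.concatenate(outs, axis=0)


def random_baseline(val_features: np.ndarray,
                    test_features: np.ndarray) -> np.ndarray:
    """Model-free baseline: Mahalanobis scores of raw feature vectors under
    the Gaussian fitted on the validation features."""
    dist = fit_error_distribution(val_features)
    return mahalanobis(test_features, dist)
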