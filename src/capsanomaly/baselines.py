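"""Non-capsule baselines: Negative Learning (NL) and the Autoencoding
Binary Classifier (ABC).

Negative Learning trains a Restricted Boltzmann Machine with single-step
contrastive divergence, flipping the sign of the update for anomalous
examples so the model's ability to reconstruct them is actively damaged:
``delta_w = sigma * E[(v h)_original - (v h)_reconstructed]`` with
``sigma = +1`` on normals and ``-1`` on anomalies, positives first within
each epoch.

ABC trains an MLP autoencoder with a per-example loss that minimizes the
reconstruction error on normals and caps the maximize-error objective on
anomalies through a log transform:
``L = y * MSE - (1 - y) * log(1 - exp(-MSE))`` (here ``y = 1`` marks a
normal example, so anomalies take the capped branch).

Both models score an input by its reconstruction error, higher meaning more
anomalous.  Inputs are flattened and min-max scaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, Adam

__all__ = ["RBMState", "ABCConfig", "cd1_update", "train_negative_learning",
           "nl_score", "abc_loss", "ABCAutoencoder", "train_abc", "flatten_01"]


def flatten_01(x: np.ndarray) -> np.ndarray:
    """Flatten examples and min-max scale the whole batch to [0, 1]."""
    x = np.asarray(x, dtype=np.float64).reshape(len(x), -1)
    lo, hi = x.min(), x.max()
    if hi > lo:
        x = (x - lo) / (hi - lo)
    else:
        x = np.zeros_like(x)
    return x


# ----------------------------------------------------------------------- RBM
@dataclass
class RBMState:
    """Bernoulli-Bernoulli RBM parameters."""

    weights: np.ndarray            # (visible, hidden)
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    @classmethod
    def init(cls, n_visible: int, n_hidden: int, seed: int = 0) -> "RBMState":
        rng = np.random.default_rng(seed)
        return cls(weights=rng.normal(0, 0.01, (n_visible, n_hidden)),
                   visible_bias=np.zeros(n_visible),
                   hidden_bias=np.zeros(n_hidden))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def cd1_update(rbm: RBMState, batch: np.ndarray, sign: int,
               learning_rate: float, seed: int = 0) -> RBMState:
    """One CD-1 step with the given sign (+1 positive, -1 negative learning).

    Hidden units are sampled stochastically on the data-driven pass (seeded);
    the reconstruction pass uses probabilities, the standard CD-1 recipe.
    Returns a new RBMState; the input is not mutated.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 1:
        batch = batch[None]
    if batch.min() < 0 or batch.max() > 1:
        raise ValueError("RBM inputs must lie in [0, 1]")
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    rng = np.random.default_rng(seed)
    v0 = batch
    ph0 = _sigmoid(v0 @ rbm.weights + rbm.hidden_bias)
    h0 = (rng.random(ph0.shape) < ph0).astype(np.float64)
    pv1 = _sigmoid(h0 @ rbm.weights.T + rbm.visible_bias)
    ph1 = _sigmoid(pv1 @ rbm.weights + rbm.hidden_bias)
    dw = (v0.T @ ph0 - pv1.T @ ph1) / len(batch)
    dvb = (v0 - pv1).mean(axis=0)
    dhb = (ph0 - ph1).mean(axis=0)
    lr = learning_rate * sign
    return RBMState(weights=rbm.weights + lr * dw,
                    visible_bias=rbm.visible_bias + lr * dvb,
                    hidden_bias=rbm.hidden_bias + lr * dhb)


def train_negative_learning(x: np.ndarray, y: np.ndarray, n_hidden: int = 32,
                            epochs: int = 10, batch_size: int = 64,
                            learning_rate: float = 0.05, seed: int = 0) -> RBMState:
    """NL training loop: per epoch, positive CD-1 on all normal examples
    first, then sign-flipped CD-1 on all anomalous examples.

    `y` uses the anomaly coding of this package: 1 = anomalous, 0 = normal.
    """
    x = flatten_01(x)
    y = np.asarray(y, dtype=int)
    rbm = RBMState.init(x.shape[1], n_hidden, seed=seed)
    rng = np.random.default_rng(seed + 1)
    pos, neg = x[y == 0], x[y == 1]
    for _ in range(epochs):
        for data, sign in ((pos, +1), (neg, -1)):
            if len(data) == 0:
                continue
            order = rng.permutation(len(data))
            for start in range(0, len(data), batch_size):
                sub = data[order[start:start + batch_size]]
                rbm = cd1_update(rbm, sub, sign, learning_rate,
                                 seed=int(rng.integers(2 ** 31)))
    return rbm


def nl_score(rbm: RBMState, x: np.ndarray) -> np.ndarray:
    """Reconstruction error under a deterministic mean-field pass.

    Probabilities are propagated (no sampling) so scoring is reproducible.
    Higher error = more anomalous.
    """
    x = flatten_01(x)
    ph = _sigmoid(x @ rbm.weights + rbm.hidden_bias)
    pv = _sigmoid(ph @ rbm.weights.T + rbm.visible_bias)
    return np.mean((x - pv) ** 2, axis=1)


# ----------------------------------------------------------------------- ABC
@dataclass
class ABCConfig:
    hidden_widths: tuple[int, ...] = (32,)
    log_clamp_eps: float = 1e-8

    def __post_init__(self):
        if self.log_clamp_eps <= 0:
            raise ValueError("log_clamp_eps must be positive")


def abc_loss(x: np.ndarray, x_hat: np.ndarray, y: int,
             eps: float = 1e-8) -> float:
    """ABC per-example loss with y = 1 normal, y = 0 anomalous.

    ``y * MSE - (1 - y) * log(1 - exp(-MSE))`` with the log argument clamped
    to [eps, 1] so a perfectly reconstructed anomaly yields a large finite
    penalty rather than infinity.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    mse = float(np.mean((x - x_hat) ** 2))
    if y == 1:
        return mse
    arg = min(max(1.0 - np.exp(-mse), eps), 1.0)
    return -float(np.log(arg))


class ABCAutoencoder:
    """Symmetric MLP autoencoder trained with the ABC objective."""

    def __init__(self, n_features: int, config: ABCConfig | None = None, seed: int = 0):
        self.config = config or ABCConfig()
        self.n_features = n_features
        rng = np.random.default_rng(seed)
        widths = [n_features, *self.config.hidden_widths]
        self.enc, self.dec = [], []
        for a, b in zip(widths[:-1], widths[1:]):
            self.enc.append((Tensor(rng.normal(0, np.sqrt(2.0 / a), (a, b)), requires_grad=True),
                             Tensor(np.zeros(b), requires_grad=True)))
        for a, b in zip(widths[::-1][:-1], widths[::-1][1:]):
            self.dec.append((Tensor(rng.normal(0, np.sqrt(2.0 / a), (a, b)), requires_grad=True),
                             Tensor(np.zeros(b), requires_grad=True)))

    @property
    def parameters(self):
        return [p for pair in self.enc + self.dec for p in pair]

    def _forward_t(self, x: np.ndarray) -> Tensor:
        h = Tensor(x)
        for w, b in self.enc:
            h = (h @ w + b).relu()
        layers = len(self.dec)
        for i, (w, b) in enumerate(self.dec):
            h = h @ w + b
            h = h.sigmoid() if i == layers - 1 else h.relu()
        return h

    def reconstruct(self, x: np.ndarray) -> np.ndarray:
        return self._forward_t(flatten_01(x)).data

    def score(self, x: np.ndarray) -> np.ndarray:
        """Reconstruction MSE per example; higher = more anomalous."""
        x = flatten_01(x)
        return np.mean((x - self._forward_t(x).data) ** 2, axis=1)


def train_abc(x: np.ndarray, y: np.ndarray, config: ABCConfig | None = None,
              epochs: int = 20, batch_size: int = 64, lr: float = 1e-3,
              seed: int = 0) -> ABCAutoencoder:
    """Train the ABC autoencoder; `y` = 1 anomalous, 0 normal.

    Internally the loss uses the ABC convention (normal branch minimizes
    MSE, anomalous branch takes the capped log term).
    """
    x = flatten_01(x)
    y = np.asarray(y, dtype=int)
    model = ABCAutoencoder(x.shape[1], config, seed=seed)
    eps = model.config.log_clamp_eps
    opt = Adam(model.parameters, lr=lr)
    rng = np.random.default_rng(seed + 1)
    for _ in range(epochs):
        order = rng.permutation(len(x))
        for start in range(0, len(x), batch_size):
            idx = order[start:start + batch_size]
            xb, yb = x[idx], y[idx]
            recon = model._forward_t(xb)
            diff = recon - Tensor(xb)
            mse = (diff * diff).mean(axis=1)                     # (B,)
            normal_mask = (yb == 0).astype(float)
            # capped branch: -log(1 - exp(-mse)) with clamped argument
            expneg = (mse * -1.0).exp()
            arg = Tensor(1.0) - expneg
            clamped = Tensor(np.clip(arg.data, eps, 1.0))
            # gradient flows only where the clamp is inactive
            active = ((arg.data > eps) & (arg.data < 1.0)).astype(float)
            log_term = (arg * Tensor(active) + clamped * Tensor(1 - active)).log()
            loss = (mse * Tensor(normal_mask) -
                    log_term * Tensor(1 - normal_mask)).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
    return model
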