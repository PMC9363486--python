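"""Two-layer capsule network with dynamic routing by agreement.

The network follows the classic construction: a convolutional preprocessing
stage, a bank of `O_P` parallel convolutional layers whose responses at each
(filter, position) site form the primary-capsule vectors, and `N_S` class
capsules reached through iterative routing.  Routing couples each primary
capsule `i` to each class capsule `j` with a coefficient `c_ij` obtained by a
softmax over routing logits; logits start at zero (uniform couplings) and are
incremented by the agreement — the scalar product between the transformed
primary output `W_ij u_i` and the class-capsule output `v_j`.

The coupling tensor is the raw material for the inequality-based anomaly
scores (see :mod:`capsanomaly.inequality`): couplings are exposed with shape
``(N_P, N_S, O_S)``, the scalar `c_ij` broadcast across the output dimension.

The class-capsule norm vector `Yhat` drives both the classification
probabilities (softmax of norms) and the margin loss; a small MLP decoder
reconstructs the input from the selected class capsule and contributes an
MSE regularization term.  With anomaly masking enabled (the default) only
normal-labeled examples contribute to the reconstruction term, so the decoder
learns to reconstruct normal data only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, Adam, conv2d, einsum, stack, softmax as t_softmax

__all__ = [
    "NetworkConfig",
    "LossConfig",
    "CapsuleNet",
    "squash",
    "class_probabilities",
    "margin_loss",
    "train",
    "save_model",
    "load_model",
]

NORMAL_CAPSULE = 0
ANOMALY_CAPSULE = 1


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


@dataclass
class NetworkConfig:
    """Architecture hyperparameters.

    ``n_parallel_layers`` is the primary-capsule output dimension ``O_P``:
    the primary stage consists of that many parallel convolutional layers of
    ``n_filters`` filters each over the shared preprocessed input, and the
    vector of primary capsule ``i`` = (filter, position) is that site's
    response across the parallel layers.  ``primary_count`` is therefore
    ``N_P = n_filters * w * h`` for the primary-stage output grid (w, h).
    """

    input_shape: tuple[int, int, int] = (1, 16, 16)  # (channels, H, W)
    preproc_filters: int = 8
    preproc_kernel: tuple[int, int] | int = 3
    preproc_stride: tuple[int, int] | int = 1
    activation: str = "relu"  # or "elu"
    n_parallel_layers: int = 8  # O_P
    n_filters: int = 8  # N_f per parallel layer
    primary_kernel: tuple[int, int] | int = 5
    primary_stride: tuple[int, int] | int = 3
    secondary_count: int = 2  # N_S
    secondary_dim: int = 16  # O_S
    routing_iterations: int = 3
    decoder_hidden: int = 64

    def __post_init__(self):
        self.input_shape = tuple(int(s) for s in self.input_shape)
        if self.secondary_count < 2:
            raise ValueError("need at least two class capsules")
        if self.routing_iterations < 1:
            raise ValueError("routing_iterations must be >= 1")
        if self.primary_count < 1:
            raise ValueError("conv geometry yields no primary capsules")

    @staticmethod
    def _out(size: int, k: int, s: int) -> int:
        return (size - k) // s + 1

    @property
    def preproc_shape(self) -> tuple[int, int]:
        _, h, w = self.input_shape
        kh, kw = _pair(self.preproc_kernel)
        sh, sw = _pair(self.preproc_stride)
        return self._out(h, kh, sh), self._out(w, kw, sw)

    @property
    def primary_grid(self) -> tuple[int, int]:
        h, w = self.preproc_shape
        kh, kw = _pair(self.primary_kernel)
        sh, sw = _pair(self.primary_stride)
        return self._out(h, kh, sh), self._out(w, kw, sw)

    @property
    def primary_count(self) -> int:
        h, w = self.primary_grid
        return self.n_filters * h * w

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LossConfig:
    """Margin-loss margins, negative down-weight and reconstruction weight."""

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_neg: float = 0.5
    alpha_recon: float = 5e-4
    mask_anomaly_reconstruction: bool = True

    def __post_init__(self):
        if not (0 < self.m_minus < self.m_plus < 1):
            raise ValueError("require 0 < m_minus < m_plus < 1")
        if self.lambda_neg < 0 or self.alpha_recon < 0:
            raise ValueError("lambda_neg and alpha_recon must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


# --------------------------------------------------------------------- squash
def squash(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squash nonlinearity: ``(|x|^2 / (1 + |x|^2)) * x / |x|``.

    Shrinks short vectors toward zero and bounds long ones below unit norm,
    preserving direction.  The zero vector maps to itself (continuity limit).
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("squash requires finite input")
    n2 = np.sum(x * x, axis=axis, keepdims=True)
    n = np.sqrt(n2)
    scale = np.divide(n, 1.0 + n2, out=np.zeros_like(n), where=n > 0)
    return x * scale


def _squash_t(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Differentiable squash (smoothed at zero by `eps`)."""
    n2 = (x * x).sum(axis=axis, keepdims=True)
    return x * (n2 / (1.0 + n2) / (n2 + eps).sqrt())


def class_probabilities(norms: np.ndarray) -> np.ndarray:
    """Class probabilities = softmax of the class-capsule output norms."""
    norms = np.asarray(norms, dtype=np.float64)
    shifted = norms - norms.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def margin_loss(norms: np.ndarray, true_class: int, cfg: LossConfig) -> float:
    """Sum over capsules of the hinge-squared margin loss.

    ``L_k = T_k relu(m+ - Yhat_k)^2 + lambda (1 - T_k) relu(Yhat_k - m-)^2``
    with ``T_k = 1`` exactly for the capsule of the true class.
    """
    norms = np.asarray(norms, dtype=np.float64)
    if not (0 <= true_class < norms.shape[-1]):
        raise IndexError(f"true_class {true_class} out of range for {norms.shape[-1]} capsules")
    t = np.zeros(norms.shape[-1])
    t[true_class] = 1.0
    pos = np.maximum(cfg.m_plus - norms, 0.0) ** 2
    neg = np.maximum(norms - cfg.m_minus, 0.0) ** 2
    return float(np.sum(t * pos + cfg.lambda_neg * (1 - t) * neg))


def route(u: np.ndarray, W: np.ndarray, iterations: int = 3,
          record_couplings: bool = False) -> dict:
    """Dynamic routing by agreement on raw arrays.

    Parameters
    ----------
    u : (N_P, O_P) squashed primary-capsule outputs.
    W : (N_P, N_S, O_S, O_P) transform tensor.
    iterations : number of routing iterations (>= 1).

    Routing logits start at zero, so the first-iteration couplings are
    uniform (1/N_S).  Each iteration computes couplings by softmax over the
    secondary axis, forms ``s_j = sum_i c_ij * (W_ij u_i)``, squashes to
    ``v_j``, and (except on the last pass) adds the agreement
    ``<W_ij u_i, v_j>`` to the logits.

    Returns a dict with ``v``, ``s``, ``norms``, scalar couplings ``c``
    of shape (N_P, N_S), the broadcast ``couplings`` (N_P, N_S, O_S),
    final ``logits`` and, optionally, the per-iteration coupling history.
    """
    u = np.asarray(u, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if iterations < 1:
        raise ValueError("need at least one routing iteration")
    n_p, o_p = u.shape
    if W.shape[0] != n_p or W.shape[3] != o_p:
        raise ValueError(f"W shape {W.shape} inconsistent with u shape {u.shape}")
    n_s, o_s = W.shape[1], W.shape[2]
    u_hat = np.einsum("insp,ip->ins", W, u)
    logits = np.zeros((n_p, n_s))
    history = []
    for r in range(iterations):
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        c = e / e.sum(axis=1, keepdims=True)
        s = np.einsum("in,ins->ns", c, u_hat)
        v = squash(s, axis=-1)
        if record_couplings:
            history.append(c.copy())
        if r < iterations - 1:
            logits = logits + np.einsum("ins,ns->in", u_hat, v)
    norms = np.linalg.norm(v, axis=-1)
    return {
        "v": v, "s": s, "norms": norms, "c": c,
        "couplings": np.repeat(c[:, :, None], o_s, axis=2),
        "logits": logits, "history": history,
    }


# ---------------------------------------------------------------------- model
class CapsuleNet:
    """Capsule network with dynamic routing and a reconstruction decoder."""

    def __init__(self, config: NetworkConfig | None = None,
                 loss_config: LossConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        self.loss_config = loss_config or LossConfig()
        self._init_params(np.random.default_rng(seed))

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        c, _, _ = cfg.input_shape
        kh, kw = _pair(cfg.preproc_kernel)
        fan = c * kh * kw
        self.pre_w = Tensor(rng.normal(0, np.sqrt(2.0 / fan),
                                       (cfg.preproc_filters, c, kh, kw)), requires_grad=True)
        self.pre_b = Tensor(np.zeros(cfg.preproc_filters), requires_grad=True)

        pkh, pkw = _pair(cfg.primary_kernel)
        fan = cfg.preproc_filters * pkh * pkw
        self.prim_w = [
            Tensor(rng.normal(0, np.sqrt(2.0 / fan),
                              (cfg.n_filters, cfg.preproc_filters, pkh, pkw)), requires_grad=True)
            for _ in range(cfg.n_parallel_layers)
        ]
        self.prim_b = [Tensor(np.zeros(cfg.n_filters), requires_grad=True)
                       for _ in range(cfg.n_parallel_layers)]

        n_p = cfg.primary_count
        self.W = Tensor(rng.normal(0, 0.1, (n_p, cfg.secondary_count,
                                            cfg.secondary_dim, cfg.n_parallel_layers)),
                        requires_grad=True)

        n_pix = int(np.prod(cfg.input_shape))
        self.dec_w1 = Tensor(rng.normal(0, np.sqrt(2.0 / cfg.secondary_dim),
                                        (cfg.secondary_dim, cfg.decoder_hidden)), requires_grad=True)
        self.dec_b1 = Tensor(np.zeros(cfg.decoder_hidden), requires_grad=True)
        self.dec_w2 = Tensor(rng.normal(0, np.sqrt(2.0 / cfg.decoder_hidden),
                                        (cfg.decoder_hidden, n_pix)), requires_grad=True)
        self.dec_b2 = Tensor(np.zeros(n_pix), requires_grad=True)

    @property
    def parameters(self) -> list[Tensor]:
        return ([self.pre_w, self.pre_b] + self.prim_w + self.prim_b +
                [self.W, self.dec_w1, self.dec_b1, self.dec_w2, self.dec_b2])

    # ------------------------------------------------------------- primaries
    def _primary(self, x: Tensor) -> Tensor:
        """Primary capsule outputs u: (B, N_P, O_P), squashed."""
        cfg = self.config
        stride = _pair(cfg.preproc_stride)
        pre = conv2d(x, self.pre_w, self.pre_b, stride)
        pre = pre.elu() if cfg.activation == "elu" else pre.relu()
        pstride = _pair(cfg.primary_stride)
        maps = [conv2d(pre, w, b, pstride) for w, b in zip(self.prim_w, self.prim_b)]
        b = x.shape[0]
        # each map: (B, N_f, h, w); capsule i = (filter, position), its vector
        # = the response at that site across the parallel layers
        u = stack([m.reshape(b, cfg.primary_count) for m in maps], axis=2)
        return _squash_t(u, axis=-1)

    # --------------------------------------------------------------- routing
    def _route(self, u: Tensor, iterations: int | None = None,
               record_couplings: bool = False):
        """Dynamic routing. u: (B, N_P, O_P). Returns (v, s, c, history).

        c has shape (B, N_P, N_S) — the scalar coupling per (primary,
        secondary) pair; downstream consumers broadcast it across O_S.
        """
        cfg = self.config
        iters = cfg.routing_iterations if iterations is None else iterations
        if iters < 1:
            raise ValueError("need at least one routing iteration")
        u_hat = einsum("insp,bip->bins", self.W, u)  # (B, N_P, N_S, O_S)
        b_sz = u.shape[0]
        logits = Tensor(np.zeros((b_sz, u.shape[1], cfg.secondary_count)))
        history = []
        c = v = s = None
        for r in range(iters):
            c = t_softmax(logits, axis=2)                      # (B, N_P, N_S)
            s = einsum("bin,bins->bns", c, u_hat)              # (B, N_S, O_S)
            v = _squash_t(s, axis=-1)
            if record_couplings:
                history.append(c.data.copy())
            if r < iters - 1:
                agreement = einsum("bins,bns->bin", u_hat, v)
                logits = logits + agreement
        return v, s, c, history

    # --------------------------------------------------------------- decoder
    def _decode(self, v: Tensor, select: np.ndarray) -> Tensor:
        """Reconstruct from the selected class capsule. select: (B,) indices."""
        b = v.shape[0]
        mask = np.zeros((b, self.config.secondary_count))
        mask[np.arange(b), select] = 1.0
        chosen = einsum("bns,bn->bs", v, Tensor(mask))          # (B, O_S)
        h = (chosen @ self.dec_w1 + self.dec_b1).relu()
        out = (h @ self.dec_w2 + self.dec_b2).sigmoid()
        return out.reshape((b,) + self.config.input_shape)

    # --------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, labels: np.ndarray | None = None,
                routing_iterations: int | None = None) -> dict:
        """Full pass: primaries -> routing -> probabilities -> reconstruction.

        Returns a dict of numpy arrays (couplings exposed, not discarded)
        plus the Tensors needed for the training objective when `labels`
        is given.
        """
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match configured {self.config.input_shape}")
        xt = Tensor(x)
        u = self._primary(xt)
        v, s, c, _ = self._route(u, routing_iterations)
        norms_t = ((v * v).sum(axis=-1) + 1e-16).sqrt()         # (B, N_S)
        norms = norms_t.data
        probs = class_probabilities(norms)
        if labels is not None:
            select = np.asarray(labels, dtype=int)
        else:
            select = probs.argmax(axis=1)
        recon_t = self._decode(v, select)
        o_s = self.config.secondary_dim
        couplings = np.repeat(c.data[:, :, :, None], o_s, axis=3)  # (B,N_P,N_S,O_S)
        return {
            "u": u.data,
            "v": v.data,
            "s": s.data,
            "norms": norms,
            "probs": probs,
            "couplings": couplings,
            "coupling_scalars": c.data,
            "reconstruction": recon_t.data,
            "_tensors": {"v": v, "norms": norms_t, "recon": recon_t, "x": xt},
        }

    # ------------------------------------------------------------------ loss
    def loss(self, x: np.ndarray, labels: np.ndarray) -> tuple[Tensor, dict]:
        """Total training objective: margin loss + alpha * masked recon MSE."""
        labels = np.asarray(labels, dtype=int)
        out = self.forward(x, labels=labels)
        t = out["_tensors"]
        cfg = self.loss_config
        b, n_s = t["norms"].shape
        onehot = np.zeros((b, n_s))
        onehot[np.arange(b), labels] = 1.0
        norms = t["norms"]
        pos = ((Tensor(onehot * cfg.m_plus) - norms * Tensor(onehot)).relu()) ** 2
        neg = ((norms * Tensor(1 - onehot) - Tensor((1 - onehot) * cfg.m_minus)).relu()) ** 2
        margin = (pos + neg * cfg.lambda_neg).sum(axis=1).mean()
        diff = t["recon"] - t["x"]
        per_ex_mse = (diff * diff).reshape(b, -1).mean(axis=1)   # (B,)
        if cfg.mask_anomaly_reconstruction:
            mask = (labels == NORMAL_CAPSULE).astype(float)
        else:
            mask = np.ones(b)
        denom = max(mask.sum(), 1.0)
        recon = (per_ex_mse * Tensor(mask)).sum() * (1.0 / denom)
        total = margin + recon * cfg.alpha_recon
        return total, {"margin": float(margin.data), "recon": float(recon.data),
                       "total": float(total.data)}


def total_loss(model: CapsuleNet, x: np.ndarray, labels: np.ndarray) -> float:
    """Scalar value of the training objective on a batch."""
    t, _ = model.loss(x, labels)
    return float(t.data)


# ------------------------------------------------------------------- training
def train(model: CapsuleNet, x: np.ndarray, labels: np.ndarray,
          epochs: int = 10, batch_size: int = 32, lr: float = 3e-3,
          seed: int = 0, verbose: bool = False) -> list[dict]:
    """Train with Adam on shuffled minibatches; returns per-epoch history.

    Reproducible under a fixed seed on fixed hardware/BLAS settings.
    """
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training split must contain both classes")
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters, lr=lr)
    history: list[dict] = []
    n = len(x)
    for epoch in range(epochs):
        order = rng.permutation(n)
        tot = marg = rec = 0.0
        nb = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss_t, parts = model.loss(x[idx], labels[idx])
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            tot += parts["total"]
            marg += parts["margin"]
            rec += parts["recon"]
            nb += 1
        entry = {"epoch": epoch, "loss": tot / nb, "margin": marg / nb, "recon": rec / nb}
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: loss={entry['loss']:.5f}")
    return history


# ---------------------------------------------------------------- checkpoints
def save_model(model: CapsuleNet, path: str) -> None:
    """Single-archive checkpoint: weight arrays + JSON configs."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters)}
    meta = json.dumps({"network": model.config.to_dict(),
                       "loss": model.loss_config.to_dict()})
    np.savez(path if str(path).endswith(".npz") else str(path) + ".npz",
             __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> CapsuleNet:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        net_d = meta["network"]
        for key in ("input_shape", "preproc_kernel", "preproc_stride",
                    "primary_kernel", "primary_stride"):
            if isinstance(net_d.get(key), list):
                net_d[key] = tuple(net_d[key])
        model = CapsuleNet(NetworkConfig(**net_d), LossConfig(**meta["loss"]))
        for i, p in enumerate(model.parameters):
            p.data = z[f"p{i}"].astype(np.float64)
    return model
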