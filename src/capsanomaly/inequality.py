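"""Anomaly and normality scores computed from a trained capsule network.

The central idea: dynamic routing polarizes — a well-trained network routes
each input through few dominant primary-to-class connections.  How unequal
the couplings into the *anomaly* class capsule are therefore carries
information about whether an input looks anomalous, and that inequality can
be measured with the statistics economists use for income distributions.

Scores implemented
------------------
``gini``        Gini coefficient of the summed couplings (higher = anomalous)
``palma``       Palma ratio Q90/Q40 of the summed couplings (higher = anomalous)
``plain``       the network's estimated anomaly-class probability
``A``           normal-capsule norm - anomaly-capsule norm + reconstruction MSE
``N_pp``        max class-capsule norm (higher = normal)
``N_re``        reconstruction MSE normalized by the input's Euclidean norm

The contribution vector fed to Gini/Palma is ``M_j[i] = sum_l c[i, j, l]`` —
the total contribution of primary capsule ``i`` to class capsule ``j``,
couplings summed over the output-dimension axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CouplingSummary",
    "ScoreRecord",
    "POLARITY",
    "PALMA_SENTINEL",
    "summed_couplings",
    "gini",
    "palma",
    "anomaly_score_A",
    "normality_pp",
    "normality_re",
    "score_batch",
    "scores_to_frame",
]

PALMA_SENTINEL = 1e12

#: score orientation used when computing AUROC: "anomalous" means larger
#: values indicate the anomalous class, "normal" the reverse.
POLARITY = {
    "gini": "anomalous",
    "palma": "anomalous",
    "plain": "anomalous",
    "A": "normal",
    "N_pp": "normal",
    "N_re": "anomalous",
    "nl": "anomalous",
    "abc": "anomalous",
}


@dataclass
class CouplingSummary:
    """Total contributions of the primary capsules to one class capsule."""

    m: np.ndarray  # length N_P
    capsule_index: int


@dataclass
class ScoreRecord:
    example_id: int
    score_name: str
    value: float
    polarity: str


def summed_couplings(couplings: np.ndarray, j: int) -> CouplingSummary:
    """Sum the coupling tensor over the output-dimension axis for capsule j.

    `couplings` has shape (N_P, N_S, O_S); the result is the length-N_P
    contribution vector M_j.
    """
    couplings = np.asarray(couplings, dtype=np.float64)
    if couplings.ndim != 3:
        raise ValueError("expected coupling tensor of shape (N_P, N_S, O_S)")
    if not (0 <= j < couplings.shape[1]):
        raise IndexError(f"capsule index {j} out of range for N_S={couplings.shape[1]}")
    return CouplingSummary(m=couplings[:, j, :].sum(axis=1), capsule_index=j)


def gini(z: np.ndarray) -> float:
    """Gini coefficient of a non-negative vector.

    Entries are sorted ascending and the sorted-index form is applied:
    ``G = sum_i (2i - n - 1) z_(i) / (n sum_i z_i)`` with 1-based ranks.
    0 for a constant vector; (n-1)/n when a single entry holds all mass,
    approaching 1 as n grows.  Scale-invariant.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    n = z.size
    if n < 2:
        raise ValueError("gini needs at least two entries")
    if np.any(z < 0):
        raise ValueError("gini requires non-negative entries")
    total = z.sum()
    if total <= 0:
        raise ValueError("gini is undefined for an all-zero vector")
    zs = np.sort(z)
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * zs) / (n * total))


def palma(z: np.ndarray, eps: float = 1e-12, return_flag: bool = False):
    """Palma ratio: 90th over 40th percentile (linear interpolation).

    Tail-sensitive inequality measure; 1.0 for a constant vector and
    scale-invariant.  If the 40th percentile falls below `eps` the ratio is
    undefined and the guarded sentinel ``PALMA_SENTINEL`` is returned (with
    ``flagged=True`` when ``return_flag``); couplings are strictly positive
    so this fires only on degenerate inputs.
    """
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.size == 0:
        raise ValueError("palma of an empty vector")
    if np.any(z < 0):
        raise ValueError("palma requires non-negative entries")
    q90 = float(np.quantile(z, 0.9))
    q40 = float(np.quantile(z, 0.4))
    if q40 < eps:
        return (PALMA_SENTINEL, True) if return_flag else PALMA_SENTINEL
    val = q90 / q40
    return (val, False) if return_flag else val


def anomaly_score_A(norms: np.ndarray, x: np.ndarray, x_hat: np.ndarray,
                    normal_index: int = 0, anomaly_index: int = 1) -> float:
    """Norm-difference anomaly measure plus reconstruction error.

    ``A = Yhat_normal - Yhat_anomaly + MSE(X, Xhat)``; large for confident
    normal examples, so its polarity is higher-is-normal.
    """
    norms = np.asarray(norms, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"input {x.shape} and reconstruction {x_hat.shape} differ")
    mse = float(np.mean((x - x_hat) ** 2))
    return float(norms[normal_index] - norms[anomaly_index] + mse)


def normality_pp(norms: np.ndarray) -> float:
    """Largest class-capsule norm: near 1 for confident normals, near 0.5
    when the two capsules cannot agree (an outlier)."""
    norms = np.asarray(norms, dtype=np.float64)
    if norms.size == 0:
        raise ValueError("empty norm vector")
    return float(norms.max())


def normality_re(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Reconstruction MSE normalized by the Euclidean norm of the input."""
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"input {x.shape} and reconstruction {x_hat.shape} differ")
    norm = float(np.sqrt(np.sum(x ** 2)))
    if norm == 0:
        raise ValueError("normality_re undefined for an all-zero input")
    return float(np.mean((x - x_hat) ** 2) / norm)


ALL_SCORES = ("gini", "palma", "plain", "A", "N_pp", "N_re")


def score_batch(model, x: np.ndarray, score_names=ALL_SCORES,
                anomaly_capsule: int = 1, batch_size: int = 256) -> list[ScoreRecord]:
    """Score every example with the requested metrics in one forward pass.

    Gini/Palma are computed on the summed couplings into the anomaly-class
    capsule; `plain` is the estimated anomaly-class probability; the rest
    come from the class-capsule norms and the reconstruction.
    """
    unknown = set(score_names) - set(ALL_SCORES)
    if unknown:
        raise ValueError(f"unknown score name(s): {sorted(unknown)}")
    x = np.asarray(x, dtype=np.float64)
    records: list[ScoreRecord] = []
    normal_capsule = 0 if anomaly_capsule != 0 else 1
    for start in range(0, len(x), batch_size):
        xb = x[start:start + batch_size]
        out = model.forward(xb)
        for b in range(len(xb)):
            eid = start + b
            coup = out["couplings"][b]
            for name in score_names:
                if name == "gini":
                    val = gini(summed_couplings(coup, anomaly_capsule).m)
                elif name == "palma":
                    val = palma(summed_couplings(coup, anomaly_capsule).m)
                elif name == "plain":
                    val = float(out["probs"][b, anomaly_capsule])
                elif name == "A":
                    val = anomaly_score_A(out["norms"][b], xb[b],
                                          out["reconstruction"][b],
                                          normal_index=normal_capsule,
                                          anomaly_index=anomaly_capsule)
                elif name == "N_pp":
                    val = normality_pp(out["norms"][b])
                else:  # N_re
                    val = normality_re(xb[b], out["reconstruction"][b])
                records.append(ScoreRecord(eid, name, float(val), POLARITY[name]))
    return records


def scores_to_frame(records: list[ScoreRecord],
                    labels: np.ndarray | None = None) -> pd.DataFrame:
    """Tidy frame of scores; columns example_id, label, score_name, value."""
    df = pd.DataFrame([{"example_id": r.example_id, "score_name": r.score_name,
                        "value": r.value, "polarity": r.polarity} for r in records])
    if labels is not None:
        lab = pd.Series(np.asarray(labels), name="label")
        df.insert(1, "label", df["example_id"].map(lab))
    return df
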