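"""Self-contained desk-scale benchmarks on the synthetic fixtures.

Each benchmark generates its fixture, trains the default capsule network on
the training partition of a stratified split, computes every capsule score
on the held-out partition (with orientation calibrated on the training
partition), trains the NL and ABC baselines on the same partition, and
returns one AUROC / average-precision row per score.

These are the package's reference experiments: small enough to run on one
CPU in about a minute, large enough (2000 normal + 200 anomalous examples)
to show the coupling-inequality scores at work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import data as dmod
from .baselines import nl_score, train_abc, train_negative_learning
from .capsnet import CapsuleNet, NetworkConfig, train
from .evaluate import auroc, average_precision, evaluate_scores, fit_orientation
from .inequality import score_batch, scores_to_frame

__all__ = ["image_benchmark", "pair_benchmark", "pair_network_config"]

def pair_network_config() -> NetworkConfig:
    """Default architecture for the (2, 4, 23) one-hot pair tensors."""
    return NetworkConfig(input_shape=(2, 4, 23), preproc_kernel=(2, 3),
                         primary_kernel=(3, 5), primary_stride=(1, 2))


def _run(x: np.ndarray, y: np.ndarray, config: NetworkConfig, seed: int,
         epochs: int, with_baselines: bool, test_fraction: float = 0.3) -> dict:
    tr, te = dmod.train_test_split_stratified(y, test_fraction, seed=seed)
    model = CapsuleNet(config, seed=seed)
    history = train(model, x[tr], y[tr], epochs=epochs, seed=seed + 1)
    train_frame = scores_to_frame(score_batch(model, x[tr]), y[tr])
    orientation = fit_orientation(train_frame)
    test_frame = scores_to_frame(score_batch(model, x[te]), y[te])
    table = evaluate_scores(test_frame, orientation)
    if with_baselines:
        rows = []
        rbm = train_negative_learning(x[tr], y[tr], epochs=10, seed=seed + 2)
        abc = train_abc(x[tr], y[tr], epochs=10, seed=seed + 3)
        for name, scores in (("nl", nl_score(rbm, x[te])),
                             ("abc", abc.score(x[te]))):
            rows.append({"score_name": name,
                         "auroc": auroc(scores, y[te]),
                         "average_precision": average_precision(scores, y[te])})
        table = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return {"table": table.set_index("score_name"), "model": model,
            "history": history, "orientation": orientation,
            "n_train": len(tr), "n_test": len(te)}


def image_benchmark(seed: int = 42, epochs: int = 10, n_per_class: int = 2000,
                    fraction: float = 0.1, with_baselines: bool = True) -> dict:
    """Standard image benchmark: parts-composed 16x16 fixture, diverse-outlier
    split (all of class 0 normal, 10% anomalies sampled from class 1)."""
    images, labels = dmod.generate_synthetic_images(
        n_classes=2, n_per_class=n_per_class, image_size=16, seed=seed)
    split = dmod.build_diverse_outlier_split(images, labels, focal_class=0,
                                             fraction=fraction, seed=seed)
    x, y = images[split.indices], split.labels
    return _run(x, y, NetworkConfig(), seed, epochs, with_baselines)


def pair_benchmark(seed: int = 42, epochs: int = 10, n_normal: int = 2000,
                   n_offtarget: int = 200, with_baselines: bool = True) -> dict:
    """Sequence-pair benchmark: synthetic gRNA-target pairs, off-targets as
    the anomalous class."""
    pairs = dmod.generate_synthetic_pairs(n_normal, n_offtarget, seed=seed)
    x, y = dmod.pairs_to_arrays(pairs)
    return _run(x, y, pair_network_config(), seed, epochs, with_baselines)
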