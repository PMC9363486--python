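"""Evaluation: AUROC / average precision, experiment grids and reports.

AUROC is the rank-based (Mann-Whitney, midrank ties) area under the ROC
curve; average precision is the step-wise precision-recall summation.  Both
take the score's polarity so that every score — whether higher values mean
"more anomalous" or "more normal" — is evaluated on the anomaly class.

A grid cell is one (dataset, setup, fraction, focal class) combination; one
model is trained per cell, all scores are computed on a held-out stratified
test partition, and results are aggregated per score as mean +/- std over
the focal classes, the convention used for multi-class anomaly benchmarks.
"""

from __future__ import annotations

import itertools
import sys
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from . import data as dmod
from .capsnet import CapsuleNet, LossConfig, NetworkConfig, train
from .inequality import ALL_SCORES, POLARITY, score_batch, scores_to_frame

__all__ = ["auroc", "average_precision", "enumerate_grid", "run_grid",
           "aggregate", "report", "evaluate_scores", "fit_orientation"]


def _orient(scores: np.ndarray, polarity: str) -> np.ndarray:
    if polarity in ("anomalous", "higher_is_anomalous"):
        return scores
    if polarity in ("normal", "higher_is_normal"):
        return -scores
    raise ValueError(f"unknown polarity {polarity!r}")


def auroc(scores: np.ndarray, labels: np.ndarray,
          polarity: str = "anomalous") -> float:
    """AUROC of the anomaly class (label 1), midrank tie handling."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both labels present")
    return float(roc_auc_score(labels, _orient(np.asarray(scores, float), polarity)))


def average_precision(scores: np.ndarray, labels: np.ndarray,
                      polarity: str = "anomalous") -> float:
    """Average precision for the anomaly class; equals the positive
    prevalence for an uninformative (constant) score."""
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("average precision needs at least one positive")
    return float(average_precision_score(labels, _orient(np.asarray(scores, float), polarity)))


def fit_orientation(train_frame: pd.DataFrame) -> dict[str, int]:
    """Calibrate score orientation on training data.

    The direction in which the coupling-inequality scores separate the two
    classes is regime-dependent (the sign of the Gini/Palma difference
    between normal and anomalous inputs is not fixed a priori), so the
    harness treats orientation as a fitted property of each trained model:
    a score whose training AUROC under its declared polarity falls below
    0.5 is flipped (-1).  Calibration uses training data only; held-out
    evaluation never sees its own labels.
    """
    orientation: dict[str, int] = {}
    for name, sub in train_frame.groupby("score_name"):
        pol = POLARITY.get(name, "anomalous")
        a = auroc(sub["value"].to_numpy(), sub["label"].to_numpy(), pol)
        orientation[name] = -1 if a < 0.5 else 1
    return orientation


def evaluate_scores(frame: pd.DataFrame,
                    orientation: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-score AUROC/AP from a tidy score frame (needs a label column).

    `orientation` optionally applies per-score sign flips fitted on
    training data (see :func:`fit_orientation`).
    """
    rows = []
    for name, sub in frame.groupby("score_name"):
        pol = POLARITY.get(name, "anomalous")
        flip = (orientation or {}).get(name, 1)
        vals = flip * sub["value"].to_numpy()
        rows.append({
            "score_name": name,
            "auroc": auroc(vals, sub["label"].to_numpy(), pol),
            "average_precision": average_precision(
                vals, sub["label"].to_numpy(), pol),
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- the grid
def enumerate_grid(datasets, setups, fractions, classes) -> list[dict]:
    """Cartesian product of experiment factors, one dict per cell."""
    return [
        {"dataset": d, "setup": s, "fraction": f, "focal_class": c}
        for d, s, f, c in itertools.product(datasets, setups, fractions, classes)
    ]


def _cell_seed(master_seed: int, cell_index: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(cell_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class GridResult:
    table: pd.DataFrame       # per (cell, score): auroc / ap
    failures: list[dict]


def run_grid(dataset_arrays: dict[str, tuple[np.ndarray, np.ndarray]],
             setups, fractions, classes, seed: int = 0,
             network_config: NetworkConfig | None = None,
             loss_config: LossConfig | None = None,
             epochs: int = 5, test_fraction: float = 0.3,
             score_names=ALL_SCORES, auto_orient: bool = True,
             resume: pd.DataFrame | None = None,
             log=sys.stderr) -> GridResult:
    """Train and evaluate one model per grid cell.

    `dataset_arrays` maps a dataset name to (images, class_labels).  Per-cell
    seeds are derived deterministically from the master seed, so reruns with
    the same seed reproduce the cell list and the models.  Passing a previous
    result table as `resume` carries its rows over and skips the cells it
    already covers.  Cell failures are collected and reported, never
    silently dropped.
    """
    cells = enumerate_grid(sorted(dataset_arrays), setups, fractions, classes)
    key_cols = ("dataset", "setup", "fraction", "focal_class")
    done: set[tuple] = set()
    rows, failures = [], []
    if resume is not None and len(resume):
        done = {tuple(r) for r in resume[list(key_cols)].itertuples(index=False)}
        rows.extend(resume.to_dict("records"))
    for k, cell in enumerate(cells):
        if tuple(cell[c] for c in key_cols) in done:
            continue
        cseed = _cell_seed(seed, k)
        try:
            images, class_labels = dataset_arrays[cell["dataset"]]
            builder = (dmod.build_diverse_outlier_split
                       if cell["setup"] == "diverse_outlier"
                       else dmod.build_diverse_inlier_split)
            split = builder(images, class_labels, cell["focal_class"],
                            cell["fraction"], seed=cseed)
            x, y = images[split.indices], split.labels
            tr, te = dmod.train_test_split_stratified(y, test_fraction, seed=cseed)
            cfg = network_config or NetworkConfig(input_shape=images.shape[1:])
            model = CapsuleNet(cfg, loss_config, seed=cseed)
            train(model, x[tr], y[tr], epochs=epochs, seed=cseed)
            orientation = None
            if auto_orient:
                train_frame = scores_to_frame(
                    score_batch(model, x[tr], score_names), y[tr])
                orientation = fit_orientation(train_frame)
            frame = scores_to_frame(score_batch(model, x[te], score_names), y[te])
            ev = evaluate_scores(frame, orientation)
            for _, r in ev.iterrows():
                rows.append({**cell, "seed": cseed, "score_name": r["score_name"],
                             "auroc": r["auroc"],
                             "average_precision": r["average_precision"]})
            if log is not None:
                print(f"[grid] cell {k + 1}/{len(cells)} done: {cell}", file=log)
        except Exception as exc:  # noqa: BLE001 - failures are reported
            failures.append({**cell, "error": str(exc)})
            if log is not None:
                print(f"[grid] cell {k + 1}/{len(cells)} FAILED: {exc}", file=log)
    return GridResult(table=pd.DataFrame(rows), failures=failures)


def aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- std of AUROC and AP per score over the focal classes."""
    group_cols = [c for c in ("dataset", "setup", "fraction", "score_name")
                  if c in table.columns]
    agg = (table.groupby(group_cols)
           .agg(auroc_mean=("auroc", "mean"), auroc_std=("auroc", "std"),
                ap_mean=("average_precision", "mean"),
                ap_std=("average_precision", "std"))
           .reset_index())
    return agg.fillna({"auroc_std": 0.0, "ap_std": 0.0})


def report(agg: pd.DataFrame, metric: str = "auroc") -> str:
    """Human-readable table, best and second-best flagged per condition.

    Ties in the mean are all marked.
    """
    if agg.empty:
        raise ValueError("empty results")
    mean_col = f"{metric}_mean"
    std_col = f"{metric}_std"
    cond_cols = [c for c in ("dataset", "setup", "fraction") if c in agg.columns]
    lines = []
    for cond, sub in (agg.groupby(cond_cols) if cond_cols else [((), agg)]):
        if not isinstance(cond, tuple):
            cond = (cond,)
        header = ", ".join(f"{k}={v}" for k, v in zip(cond_cols, cond)) or "all"
        lines.append(header)
        top = sorted(sub[mean_col].unique(), reverse=True)[:2]
        for _, r in sub.sort_values(mean_col, ascending=False).iterrows():
            mark = "**" if r[mean_col] == top[0] else (
                "*" if len(top) > 1 and r[mean_col] == top[1] else "  ")
            lines.append(f"  {mark:2s} {r['score_name']:>6s}  "
                         f"{r[mean_col]:.4f} +/- {r[std_col]:.4f}")
        lines.append("")
    return "\n".join(lines)
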