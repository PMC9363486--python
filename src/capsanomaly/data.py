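"""Experiment splits, CRISPR pair encoding, file I/O and synthetic fixtures.

Two split constructions turn a multi-class dataset into a supervised
anomaly-detection problem:

* **diverse outlier** — one class is the normal set (label 0) and a small
  fraction of examples sampled from all other classes form a heterogeneous
  anomaly set (label 1);
* **diverse inlier** — one class is the (coherent) anomaly set (label 1)
  and examples sampled from all the other classes form the normal set
  (label 0).

For the CRISPR-Cas9 off-target task, a gRNA-target pair is two 23-nt
strings over {A, C, G, T}; pairs are one-hot encoded into a (2, 4, 23)
tensor (channel 0 target, channel 1 gRNA; rows in A, C, G, T order) and
pairs with more than 6 positional mismatches are discarded, since cleavage
is considered impossible beyond that.

The synthetic generators emulate the structure the methods rely on: images
composed of part motifs where the rare class uses motifs absent from the
common class, and sequence pairs whose label correlates with the positional
pattern of mismatches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "SplitSpec", "GRNATargetPair", "NUCLEOTIDES",
    "build_diverse_outlier_split", "build_diverse_inlier_split",
    "train_test_split_stratified",
    "mismatch_count", "encode_pair", "decode_pair", "filter_pairs",
    "generate_synthetic_images", "generate_synthetic_pairs",
    "read_image_dataset", "write_image_dataset",
    "read_pairs_tsv", "write_pairs_tsv", "pairs_to_arrays",
]

NUCLEOTIDES = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
PAIR_LENGTH = 23


# -------------------------------------------------------------------- splits
@dataclass
class SplitSpec:
    """A fully-resolved anomaly-detection experiment split.

    `indices` point into the source dataset; `labels` are the binary
    anomaly labels (1 = anomalous) aligned with `indices`.
    """

    setup: str                    # "diverse_outlier" | "diverse_inlier"
    focal_class: int
    anomaly_fraction: float
    seed: int
    indices: np.ndarray
    labels: np.ndarray

    def to_manifest(self) -> str:
        d = asdict(self)
        d["indices"] = self.indices.tolist()
        d["labels"] = self.labels.tolist()
        return json.dumps(d)

    @classmethod
    def from_manifest(cls, text: str) -> "SplitSpec":
        d = json.loads(text)
        d["indices"] = np.asarray(d["indices"], dtype=int)
        d["labels"] = np.asarray(d["labels"], dtype=int)
        return cls(**d)


def build_diverse_outlier_split(images: np.ndarray, labels: np.ndarray,
                                focal_class: int, fraction: float,
                                seed: int = 0) -> SplitSpec:
    """All focal-class examples become the normal set (label 0); A =
    round(fraction * focal count) examples drawn uniformly without
    replacement from the other classes become the anomalies (label 1)."""
    labels = np.asarray(labels)
    focal_idx = np.flatnonzero(labels == focal_class)
    other_idx = np.flatnonzero(labels != focal_class)
    if len(focal_idx) == 0:
        raise ValueError(f"focal class {focal_class} not present")
    n_anom = int(round(fraction * len(focal_idx)))
    if n_anom == 0:
        raise ValueError(
            f"fraction {fraction} of {len(focal_idx)} normal examples rounds to zero anomalies")
    if n_anom > len(other_idx):
        raise ValueError("not enough non-focal examples to sample anomalies")
    rng = np.random.default_rng(seed)
    anom_idx = rng.choice(other_idx, size=n_anom, replace=False)
    indices = np.concatenate([focal_idx, anom_idx])
    lab = np.concatenate([np.zeros(len(focal_idx), dtype=int),
                          np.ones(n_anom, dtype=int)])
    return SplitSpec("diverse_outlier", int(focal_class), float(fraction),
                     int(seed), indices, lab)


def build_diverse_inlier_split(images: np.ndarray, labels: np.ndarray,
                               focal_class: int, fraction: float,
                               seed: int = 0) -> SplitSpec:
    """The focal class becomes the anomaly set (label 1) in full; the normal
    set (label 0) is sampled from the other classes so the anomaly share is
    about `fraction` — round(focal count / fraction) normals, capped at
    availability."""
    labels = np.asarray(labels)
    focal_idx = np.flatnonzero(labels == focal_class)
    other_idx = np.flatnonzero(labels != focal_class)
    if len(focal_idx) == 0:
        raise ValueError(f"focal class {focal_class} not present")
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    n_norm = min(int(round(len(focal_idx) / fraction)), len(other_idx))
    if n_norm == 0:
        raise ValueError("no normal examples available")
    rng = np.random.default_rng(seed)
    norm_idx = rng.choice(other_idx, size=n_norm, replace=False)
    indices = np.concatenate([norm_idx, focal_idx])
    lab = np.concatenate([np.zeros(n_norm, dtype=int),
                          np.ones(len(focal_idx), dtype=int)])
    return SplitSpec("diverse_inlier", int(focal_class), float(fraction),
                     int(seed), indices, lab)


def train_test_split_stratified(labels: np.ndarray, test_fraction: float = 0.3,
                                seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Index split stratified by label; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_test = max(1, int(round(test_fraction * len(idx))))
        test.append(idx[:n_test])
        train.append(idx[n_test:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


# ------------------------------------------------------------- CRISPR pairs
@dataclass
class GRNATargetPair:
    target: str
    grna: str
    label: int  # 0 = no cleavage, 1 = off-target
    mismatches: int = field(default=-1)

    def __post_init__(self):
        for name, s in (("target", self.target), ("grna", self.grna)):
            if len(s) != PAIR_LENGTH:
                raise ValueError(f"{name} must be {PAIR_LENGTH} nt, got {len(s)}")
            for pos, ch in enumerate(s):
                if ch not in _NT_INDEX:
                    raise ValueError(f"invalid character {ch!r} in {name} at position {pos}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.mismatches < 0:
            self.mismatches = mismatch_count(self.target, self.grna)


def mismatch_count(a: str, b: str) -> int:
    """Number of positions at which two equal-length strings differ."""
    if len(a) != len(b):
        raise ValueError("strings must have equal length")
    return sum(x != y for x, y in zip(a, b))


def encode_pair(pair: GRNATargetPair) -> np.ndarray:
    """One-hot encode a pair into a (2, 4, 23) tensor.

    Channel 0 = target, channel 1 = gRNA; row order A, C, G, T; every
    column of each channel sums to exactly 1.
    """
    out = np.zeros((2, 4, PAIR_LENGTH))
    for ch, seq in enumerate((pair.target, pair.grna)):
        for pos, letter in enumerate(seq):
            out[ch, _NT_INDEX[letter], pos] = 1.0
    return out


def decode_pair(tensor: np.ndarray, label: int = 0) -> GRNATargetPair:
    """Inverse of :func:`encode_pair` (for round-trip validation)."""
    tensor = np.asarray(tensor)
    if tensor.shape != (2, 4, PAIR_LENGTH):
        raise ValueError(f"expected shape (2, 4, {PAIR_LENGTH}), got {tensor.shape}")
    seqs = []
    for ch in range(2):
        cols = tensor[ch].argmax(axis=0)
        seqs.append("".join(NUCLEOTIDES[i] for i in cols))
    return GRNATargetPair(target=seqs[0], grna=seqs[1], label=label)


def filter_pairs(pairs: list[GRNATargetPair],
                 max_mismatches: int = 6) -> list[GRNATargetPair]:
    """Keep pairs with at most `max_mismatches` positional mismatches,
    preserving order (off-target cleavage is considered impossible past 6)."""
    return [p for p in pairs if p.mismatches <= max_mismatches]


# ------------------------------------------------------- synthetic fixtures
# part motifs on a 5x5 stamp; classes are composed of 2-3 of these
_MOTIFS = {
    "hbar": np.array([[0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 0],
                      [1, 1, 1, 1, 1],
                      [0, 0, 0, 0, 0],
                      [0, 0, 0, 0, 0]], dtype=float),
    "vbar": np.array([[0, 0, 1, 0, 0]] * 5, dtype=float),
    "diag": np.eye(5),
    "corner": np.array([[1, 1, 1, 0, 0],
                        [1, 0, 0, 0, 0],
                        [1, 0, 0, 0, 0],
                        [0, 0, 0, 0, 0],
                        [0, 0, 0, 0, 0]], dtype=float),
    "cross": np.array([[0, 0, 1, 0, 0],
                       [0, 0, 1, 0, 0],
                       [1, 1, 1, 1, 1],
                       [0, 0, 1, 0, 0],
                       [0, 0, 1, 0, 0]], dtype=float),
    "blob": np.array([[0, 1, 1, 1, 0],
                      [1, 1, 1, 1, 1],
                      [1, 1, 1, 1, 1],
                      [1, 1, 1, 1, 1],
                      [0, 1, 1, 1, 0]], dtype=float),
    "anti": np.fliplr(np.eye(5)),
    "tee": np.array([[1, 1, 1, 1, 1],
                     [0, 0, 1, 0, 0],
                     [0, 0, 1, 0, 0],
                     [0, 0, 1, 0, 0],
                     [0, 0, 1, 0, 0]], dtype=float),
}
_MOTIF_NAMES = list(_MOTIFS)

# per-class motif sets: consecutive disjoint triples, so distinct classes
# share at most one motif (classes beyond 2 wrap with stride 2)
_CLASS_MOTIFS = [
    ("hbar", "vbar", "blob"),
    ("diag", "corner", "tee"),
    ("cross", "anti", "hbar"),
    ("vbar", "tee", "diag"),
]


def generate_synthetic_images(n_classes: int = 2, n_per_class: int = 1000,
                              image_size: int = 16, seed: int = 0,
                              noise: float = 0.15, jitter: int = 2
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Parts-composed image fixture: each class is a fixed arrangement of
    2-3 motifs with jittered positions, per-motif intensity variation and
    additive Gaussian pixel noise.

    Emulates the part-whole premise behind capsule anomaly detection: a rare
    class is built from part motifs largely absent from the common class.
    The defaults (noise sigma 0.15, position jitter of +/-2 pixels, motif
    intensity drawn in [0.6, 1.0]) keep individual parts clearly visible but
    make single-pixel evidence unreliable, the regime real benchmark images
    occupy.  Returns (images, labels); images have shape
    (N, 1, size, size) in [0, 1].
    """
    if image_size < 12:
        raise ValueError("image_size must be at least 12")
    if n_classes > len(_CLASS_MOTIFS):
        raise ValueError(f"at most {len(_CLASS_MOTIFS)} synthetic classes supported")
    rng = np.random.default_rng(seed)
    anchors = [(1, 1), (image_size - 6, image_size - 6), (1, image_size - 6)]
    images, labels = [], []
    for cls in range(n_classes):
        motifs = [_MOTIFS[m] for m in _CLASS_MOTIFS[cls]]
        for _ in range(n_per_class):
            img = np.zeros((image_size, image_size))
            for (ay, ax), stamp in zip(anchors, motifs):
                dy, dx = rng.integers(-jitter, jitter + 1, size=2)
                y = int(np.clip(ay + dy, 0, image_size - 5))
                x = int(np.clip(ax + dx, 0, image_size - 5))
                gain = rng.uniform(0.6, 1.0)
                img[y:y + 5, x:x + 5] = np.maximum(img[y:y + 5, x:x + 5], gain * stamp)
            if noise > 0:
                img = img + rng.normal(0, noise, img.shape)
            images.append(np.clip(img, 0.0, 1.0))
            labels.append(cls)
    images = np.asarray(images)[:, None, :, :]
    labels = np.asarray(labels, dtype=int)
    perm = rng.permutation(len(labels))
    return images[perm], labels[perm]


def generate_synthetic_pairs(n_normal: int = 1000, n_offtarget: int = 100,
                             seed: int = 0) -> list[GRNATargetPair]:
    """Synthetic gRNA-target pairs whose label is learnable from the
    positional mismatch pattern.

    Off-target pairs (label 1) carry 1-6 mismatches concentrated PAM-distal
    (positions 0-9 of the 20-nt protospacer); normal pairs (label 0) carry
    1-6 mismatches placed uniformly along the protospacer and their targets
    are GC-biased, giving the classes distinct composition.  All pairs pass
    the <= 6 mismatch filter by construction.
    """
    if n_normal < 1 or n_offtarget < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: list[GRNATargetPair] = []

    def mutate(seq: list[str], positions: np.ndarray) -> list[str]:
        out = list(seq)
        for p in positions:
            out[p] = rng.choice([c for c in NUCLEOTIDES if c != seq[p]])
        return out

    for label, count in ((0, n_normal), (1, n_offtarget)):
        for _ in range(count):
            if label == 0:
                # GC-biased composition for the normal class
                probs = np.array([0.15, 0.35, 0.35, 0.15])
            else:
                probs = np.array([0.25, 0.25, 0.25, 0.25])
            core = rng.choice(list(NUCLEOTIDES), size=20, p=probs)
            target = list(core) + ["A", "G", "G"]  # NGG-style PAM tail
            k = int(rng.integers(1, 7))
            if label == 1:
                pos = rng.choice(10, size=min(k, 10), replace=False)
            else:
                pos = rng.choice(20, size=k, replace=False)
            grna = mutate(target[:20], pos) + target[20:]
            pairs.append(GRNATargetPair("".join(target), "".join(grna), label))
    perm = rng.permutation(len(pairs))
    return [pairs[i] for i in perm]


def pairs_to_arrays(pairs: list[GRNATargetPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded pairs into (N, 2, 4, 23) with aligned labels."""
    x = np.stack([encode_pair(p) for p in pairs])
    y = np.asarray([p.label for p in pairs], dtype=int)
    return x, y


# ------------------------------------------------------------------ file IO
def write_image_dataset(path: str | Path, images: np.ndarray,
                        labels: np.ndarray, fmt: str = "npz") -> None:
    """Write images as an NPZ bundle or a directory of per-class PNGs."""
    path = Path(path)
    if fmt == "npz":
        np.savez(path, images=images, labels=labels)
        return
    if fmt != "png":
        raise ValueError("fmt must be 'npz' or 'png'")
    for i, (img, lab) in enumerate(zip(images, labels)):
        d = path / str(int(lab))
        d.mkdir(parents=True, exist_ok=True)
        arr = np.squeeze(np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(d / f"{i:06d}.png")


def read_image_dataset(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a directory-per-class PNG tree or an NPZ bundle.

    Returns (images, labels); images are float64 in [0, 1] with an explicit
    channel axis (N, C, H, W).
    """
    path = Path(path)
    if path.is_file() or str(path).endswith(".npz"):
        with np.load(path) as z:
            if "images" not in z or "labels" not in z:
                raise ValueError(f"{path} must contain 'images' and 'labels' arrays")
            images = np.asarray(z["images"], dtype=np.float64)
            labels = np.asarray(z["labels"], dtype=int)
    else:
        if not path.is_dir():
            raise FileNotFoundError(f"{path} is neither a file nor a directory")
        class_dirs = sorted(d for d in path.iterdir() if d.is_dir())
        if not class_dirs:
            raise ValueError(f"no class subdirectories under {path}")
        imgs, labs = [], []
        for d in class_dirs:
            files = sorted(d.glob("*.png"))
            if not files:
                raise ValueError(f"class directory {d} contains no PNG files")
            for f in files:
                arr = np.asarray(Image.open(f), dtype=np.float64) / 255.0
                imgs.append(arr)
            labs.extend([int(d.name)] * len(files))
        images = np.stack(imgs)
        labels = np.asarray(labs, dtype=int)
    if images.ndim == 3:
        images = images[:, None, :, :]
    elif images.ndim == 4 and images.shape[-1] in (1, 3) and images.shape[1] not in (1, 3):
        images = np.moveaxis(images, -1, 1)
    return images, labels


def write_pairs_tsv(path: str | Path, pairs: list[GRNATargetPair]) -> None:
    df = pd.DataFrame([{"target": p.target, "grna": p.grna, "label": p.label}
                       for p in pairs])
    df.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str | Path) -> list[GRNATargetPair]:
    """Read a TSV with columns target/grna/label; malformed rows are
    reported with their line number."""
    df = pd.read_csv(path, sep="\t", dtype={"target": str, "grna": str})
    missing = {"target", "grna", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(GRNATargetPair(str(row["target"]), str(row["grna"]),
                                        int(row["label"])))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return pairs
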