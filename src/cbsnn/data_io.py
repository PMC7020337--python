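"""Dataset readers, the synthetic cluster generator, and split/normalisation.

Supported sources: IDX image/label files (the MNIST on-disk dialect), CSV
feature tables with a label column, and a built-in synthetic generator that
produces Gaussian class clusters plus a controllable fraction of "hard"
samples drawn midway between class means — so that after one training epoch
a nontrivial subpopulation remains novel, which is what the curiosity
scheduler exploits.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "read_idx", "read_csv_dataset", "synth_clusters",
           "train_test_split", "write_idx"]

_IDX_IMAGES_MAGIC = 0x00000803
_IDX_LABELS_MAGIC = 0x00000801


@dataclass
class LabeledDataset:
    """Feature matrix in [0, 1] with integer labels.

    ``features`` has shape (n_samples, n_dims); labels lie in
    [0, n_classes).  ``name`` tags the source; ``split`` optionally marks
    train/test membership per sample.
    """

    features: np.ndarray
    labels: np.ndarray
    name: str = "dataset"
    split: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.validate()

    def validate(self) -> None:
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.features.shape[0]} feature rows but "
                f"{self.labels.shape[0]} labels")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature values")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("negative label codes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_dims(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def subset(self, idx: np.ndarray, name: str | None = None) -> "LabeledDataset":
        return LabeledDataset(self.features[idx], self.labels[idx],
                              name or self.name)


def _minmax(features: np.ndarray,
            stats: tuple[np.ndarray, np.ndarray] | None = None
            ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Per-feature min-max scaling; constant columns map to zero."""
    if stats is None:
        lo, hi = features.min(axis=0), features.max(axis=0)
    else:
        lo, hi = stats
    rng = hi - lo
    safe = np.where(rng == 0, 1.0, rng)
    scaled = np.clip((features - lo) / safe, 0.0, 1.0)
    scaled[:, rng == 0] = 0.0
    return scaled, (lo, hi)


def read_idx(images_path: str | Path, labels_path: str | Path,
             name: str = "idx") -> LabeledDataset:
    """Read an IDX image/label file pair (big-endian MNIST dialect).

    Pixels are scaled to [0, 1]; images are flattened row-major (784
    features for 28x28).
    """
    images_path, labels_path = Path(images_path), Path(labels_path)
    img_raw = images_path.read_bytes()
    if len(img_raw) < 16:
        raise ValueError(f"{images_path}: truncated IDX image header")
    magic, n, rows, cols = struct.unpack(">IIII", img_raw[:16])
    if magic != _IDX_IMAGES_MAGIC:
        raise ValueError(
            f"{images_path}: bad magic 0x{magic:08x}, "
            f"expected 0x{_IDX_IMAGES_MAGIC:08x}")
    expected = 16 + n * rows * cols
    if len(img_raw) != expected:
        raise ValueError(
            f"{images_path}: expected {expected} bytes, got {len(img_raw)}")
    pixels = np.frombuffer(img_raw, dtype=np.uint8, offset=16)
    features = pixels.reshape(n, rows * cols).astype(float) / 255.0

    lbl_raw = labels_path.read_bytes()
    if len(lbl_raw) < 8:
        raise ValueError(f"{labels_path}: truncated IDX label header")
    lmagic, ln = struct.unpack(">II", lbl_raw[:8])
    if lmagic != _IDX_LABELS_MAGIC:
        raise ValueError(
            f"{labels_path}: bad magic 0x{lmagic:08x}, "
            f"expected 0x{_IDX_LABELS_MAGIC:08x}")
    if ln != n:
        raise ValueError(f"label count {ln} != image count {n}")
    if len(lbl_raw) != 8 + ln:
        raise ValueError(f"{labels_path}: truncated label data")
    labels = np.frombuffer(lbl_raw, dtype=np.uint8, offset=8).astype(int)
    return LabeledDataset(features, labels, name=name)


def write_idx(images: np.ndarray, labels: np.ndarray,
              images_path: str | Path, labels_path: str | Path) -> None:
    """Write an IDX pair (testing aid; round-trips with :func:`read_idx`)."""
    images = np.asarray(images)
    n, rows, cols = images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">IIII", _IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(images.astype(np.uint8).tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">II", _IDX_LABELS_MAGIC, len(labels)))
        fh.write(np.asarray(labels).astype(np.uint8).tobytes())


def read_csv_dataset(path: str | Path, label_column: str,
                     name: str | None = None) -> LabeledDataset:
    """Read a headered CSV; labels factorized in order of first appearance,
    features min-max normalized per column."""
    path = Path(path)
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise ValueError(f"{path}: no column {label_column!r}")
    feat_cols = [c for c in df.columns if c != label_column]
    feats = df[feat_cols]
    bad = feats.columns[~feats.apply(
        lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(feats[col], errors="coerce").isna().idxmax())
        raise ValueError(
            f"{path}: non-numeric feature value at row {row}, column {col!r}")
    features, _ = _minmax(feats.to_numpy(dtype=float))
    labels, _ = pd.factorize(df[label_column])
    return LabeledDataset(features, labels.astype(int),
                          name=name or path.stem)


def synth_clusters(n_classes: int = 3, n_per_class: int = 200, dims: int = 4,
                   separation: float = 6.0, overlap_fraction: float = 0.2,
                   seed: int = 0) -> LabeledDataset:
    """Gaussian class clusters with a hard 'overlap' subpopulation.

    Class means sit on the vertices of a simplex scaled by ``separation``
    (unit-variance Gaussian cores).  A fraction ``overlap_fraction`` of each
    class's samples is instead drawn around the midpoint between that class's
    mean and an adjacent class's mean — these ambiguous points stay novel
    longer under training, giving the curiosity scheduler something to select.
    Features are min-max normalized; fully deterministic per seed.
    """
    if n_classes <= 0 or n_per_class <= 0 or dims <= 0:
        raise ValueError("counts must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    # simplex-like vertex placement: orthonormal-ish directions in `dims`
    means = np.zeros((n_classes, dims))
    for c in range(n_classes):
        means[c, c % dims] = separation
        means[c] += separation * 0.25 * (c // dims)
    X, y = [], []
    for c in range(n_classes):
        n_hard = int(round(overlap_fraction * n_per_class))
        n_core = n_per_class - n_hard
        X.append(means[c] + rng.standard_normal((n_core, dims)))
        if n_hard:
            other = (c + 1) % n_classes
            mid = 0.5 * (means[c] + means[other])
            X.append(mid + rng.standard_normal((n_hard, dims)))
        y.append(np.full(n_per_class, c))
    features = np.vstack(X)
    labels = np.concatenate(y)
    perm = rng.permutation(len(labels))
    features, _ = _minmax(features[perm])
    return LabeledDataset(features, labels[perm], name="synthetic")


def train_test_split(dataset: LabeledDataset, test_fraction: float,
                     seed: int = 0) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified, disjoint, exhaustive split; deterministic per seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in np.unique(dataset.labels):
        members = np.flatnonzero(dataset.labels == c)
        if members.size < 2:
            raise ValueError(
                f"class {c} has {members.size} sample(s); need >= 2 to stratify")
        members = rng.permutation(members)
        n_test = int(round(test_fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        test_idx.append(members[:n_test])
        train_idx.append(members[n_test:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))
    return (dataset.subset(tr, f"{dataset.name}-train"),
            dataset.subset(te, f"{dataset.name}-test"))
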