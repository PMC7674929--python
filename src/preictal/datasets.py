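"""Dataset assembly: clinically ranked channel selection, class balancing,
and the stratified 6:2:2 train/validation/test split.

The interictal class always outnumbers the preictal class, so a random
under-sampling step discards majority examples to an exact 1:1 ratio before
splitting.  Per-channel standardization statistics are fit on the training
indices only and applied everywhere — never recomputed on validation/test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RankedMontage",
    "LabeledDataset",
    "SplitAssignment",
    "Standardizer",
    "select_top_channels",
    "undersample_balance",
    "split_dataset",
]

INTERICTAL, PREICTAL = 0, 1
ALLOWED_K = (4, 8, 16, "all")


@dataclass(frozen=True)
class RankedMontage:
    """Channel names ordered by clinical significance, most significant first."""

    ranked_channels: tuple[str, ...]

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranked_channels[:k]


@dataclass
class LabeledDataset:
    """Featurized epochs: X (n, channels, T, F); y in {0 interictal, 1 preictal}."""

    X: np.ndarray
    y: np.ndarray
    start_s: np.ndarray
    channel_names: list[str]
    freq_bins: np.ndarray
    seed_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on sample count")
        if self.X.ndim != 4 or self.X.shape[1] != len(self.channel_names):
            raise ValueError("X must be (n, channels, T, F) matching channel_names")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def class_counts(self) -> tuple[int, int]:
        return int(np.sum(self.y == INTERICTAL)), int(np.sum(self.y == PREICTAL))

    def take(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.start_s[idx],
                              list(self.channel_names), self.freq_bins, dict(self.seed_log))


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint train/val/test index sets covering all samples."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def validate(self, n: int) -> None:
        allidx = np.concatenate([self.train, self.val, self.test])
        if len(np.unique(allidx)) != len(allidx) or len(allidx) != n:
            raise AssertionError("split sets must be disjoint and cover all indices")


def select_top_channels(dataset: LabeledDataset, montage: RankedMontage,
                        k: int | str) -> LabeledDataset:
    """Keep the top-k clinically ranked channels, in ranking order.

    k='all' is the identity (up to channel reordering by rank).  Values of k
    outside the protocol's {4, 8, 16, all} are allowed for research use.
    """
    if sorted(montage.ranked_channels) != sorted(dataset.channel_names):
        raise ValueError("montage ranking is not a permutation of the dataset's channels")
    if k == "all":
        k = len(montage.ranked_channels)
    k = int(k)
    if k > len(dataset.channel_names):
        raise ValueError(f"k={k} exceeds channel count {len(dataset.channel_names)}")
    if k < 1:
        raise ValueError("k must be >= 1")
    names = list(montage.top(k))
    idx = [dataset.channel_names.index(name) for name in names]
    return LabeledDataset(dataset.X[:, idx], dataset.y, dataset.start_s, names,
                          dataset.freq_bins, dict(dataset.seed_log))


def undersample_balance(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Randomly under-sample the majority class to an exact 1:1 ratio.

    The minority class is untouched; the majority class is subsampled without
    replacement.  Reproducible given `seed`.
    """
    n0, n1 = dataset.class_counts
    for cls, cnt in ((INTERICTAL, n0), (PREICTAL, n1)):
        if cnt == 0:
            name = "interictal" if cls == INTERICTAL else "preictal"
            raise ValueError(f"cannot balance: the {name} class is empty")
    rng = np.random.default_rng(seed)
    minority = min(n0, n1)
    keep: list[np.ndarray] = []
    for cls in (INTERICTAL, PREICTAL):
        idx = np.flatnonzero(dataset.y == cls)
        if idx.size > minority:
            idx = rng.choice(idx, size=minority, replace=False)
        keep.append(np.sort(idx))
    out = dataset.take(np.concatenate(keep))
    out.seed_log["undersample_seed"] = seed
    return out


def split_dataset(dataset: LabeledDataset, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                  seed: int = 0, mode: str = "epoch") -> SplitAssignment:
    """Seeded, stratified 6:2:2 split.

    ``mode="epoch"`` assigns epochs uniformly at random (the protocol's
    default).  ``mode="block"`` assigns contiguous time blocks per class
    (circularly rotated by the seed): overlapping preictal epochs make
    epoch-level splits optimistic — near-duplicate segments land on both
    sides of the split — so block mode is the honest choice whenever epochs
    overlap.  Stratification keeps the 1:1 class ratio within each subset
    (within one epoch).  Requires at least 5 epochs per class.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if mode not in ("epoch", "block"):
        raise ValueError(f"unknown split mode {mode!r}")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    for cls in (INTERICTAL, PREICTAL):
        idx = np.flatnonzero(dataset.y == cls)
        if idx.size < 5:
            raise ValueError(f"fewer than 5 epochs in class {cls}")
        if mode == "epoch":
            idx = rng.permutation(idx)
        else:
            order = np.argsort(dataset.start_s[idx], kind="stable")
            idx = np.roll(idx[order], int(rng.integers(idx.size)))
        n_tr = int(np.floor(idx.size * ratios[0] + 0.5))
        n_val = int(np.floor(idx.size * (ratios[0] + ratios[1]) + 0.5)) - n_tr
        parts["train"].append(idx[:n_tr])
        parts["val"].append(idx[n_tr : n_tr + n_val])
        parts["test"].append(idx[n_tr + n_val :])
    assignment = SplitAssignment(
        train=np.sort(np.concatenate(parts["train"])),
        val=np.sort(np.concatenate(parts["val"])),
        test=np.sort(np.concatenate(parts["test"])),
    )
    assignment.validate(dataset.n)
    dataset.seed_log["split_seed"] = seed
    return assignment


class Standardizer:
    """Per-channel zero-mean/unit-variance scaling fit on the training split only."""

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    def fit(self, X_train: np.ndarray) -> "Standardizer":
        # statistics over (epochs, time, frequency) per channel
        self.mean_ = X_train.mean(axis=(0, 2, 3), keepdims=True)
        std = X_train.std(axis=(0, 2, 3), keepdims=True)
        self.std_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer used before fit")
        return ((X - self.mean_) / self.std_).astype(X.dtype, copy=False)

    def fit_transform(self, X_train: np.ndarray) -> np.ndarray:
        return self.fit(X_train).transform(X_train)
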