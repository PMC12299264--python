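"""Dataset preparation: zero-row exclusion, balancing, splitting, Z-score.

The pipeline order is fixed: windows containing corrupted (all-zero)
time rows are removed first, classes are then balanced by truncation to
the minority count, the balanced set is split 70/15/15 stratified by
class, and finally every value is standardized per activity class and
sensor channel, x_norm = (x - mu_ic) / sigma_ic, with the statistics
computed over all data points of that (class, channel) pair.

Note the per-class normalization intentionally uses the class label;
``train_only_stats=True`` computes the statistics from the training
partition only, as a leakage-free alternative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synthetic import N_CHANNELS, LabeledDataset, SensorWindow

__all__ = [
    "EmptyDatasetError",
    "DegenerateChannelError",
    "ChannelStats",
    "SplitDataset",
    "filter_zero_rows",
    "balance_classes",
    "split_dataset",
    "zscore_per_class",
    "unnormalize",
    "preprocess",
]


class EmptyDatasetError(ValueError):
    """All windows were excluded; carries the exclusion report."""

    def __init__(self, message: str, report: list[str]):
        super().__init__(message)
        self.report = report


class DegenerateChannelError(ValueError):
    """A (class, channel) pair has zero variance."""


@dataclass
class ChannelStats:
    """Per-(class, channel) mean and population standard deviation."""

    class_ids: list[int]
    mu: np.ndarray      # (n_classes, N_CHANNELS)
    sigma: np.ndarray   # (n_classes, N_CHANNELS)

    def row(self, class_id: int) -> int:
        return self.class_ids.index(class_id)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "class_ids": self.class_ids,
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ChannelStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            class_ids=[int(c) for c in d["class_ids"]],
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
        )


@dataclass
class SplitDataset:
    """Train/val/test partition, optionally carrying normalization stats."""

    train: LabeledDataset
    val: LabeledDataset
    test: LabeledDataset
    split_seed: int
    stats: ChannelStats | None = None

    def parts(self) -> dict[str, LabeledDataset]:
        return {"train": self.train, "val": self.val, "test": self.test}

    def all_windows(self) -> list[SensorWindow]:
        return self.train.windows + self.val.windows + self.test.windows


def _has_zero_row(values: np.ndarray) -> bool:
    return bool(np.any(np.all(values == 0.0, axis=1)))


def filter_zero_rows(dataset: LabeledDataset) -> tuple[LabeledDataset, list[str]]:
    """Drop windows containing any time row that is zero on all channels.

    Returns the retained dataset and the list of removed window_ids.
    Raises :class:`EmptyDatasetError` if nothing survives.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("input dataset is empty", [])
    kept, removed = [], []
    for w in dataset.windows:
        if _has_zero_row(w.values):
            removed.append(w.window_id)
        else:
            kept.append(w)
    if not kept:
        raise EmptyDatasetError(
            f"all {len(dataset)} windows contained zero rows", removed
        )
    prov = dict(dataset.provenance)
    prov["excluded_zero_rows"] = removed
    return LabeledDataset(kept, dict(dataset.class_names), prov), removed


def balance_classes(dataset: LabeledDataset, seed: int) -> LabeledDataset:
    """Truncate every class to the minority-class count (seeded draw).

    The retained subset per class is a uniform draw without
    replacement; the original window order is otherwise preserved.
    """
    counts = dataset.class_counts()
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        names = [dataset.class_names[c] for c in empty]
        raise ValueError(f"classes with zero windows: {names}")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep_ids: set[str] = set()
    for class_id in sorted(counts):
        ids = [w.window_id for w in dataset.windows if w.label == class_id]
        chosen = rng.choice(len(ids), size=n_min, replace=False)
        keep_ids.update(ids[i] for i in chosen)
    kept = [w for w in dataset.windows if w.window_id in keep_ids]
    prov = dict(dataset.provenance)
    prov["balanced_to"] = n_min
    return LabeledDataset(kept, dict(dataset.class_names), prov)


def split_dataset(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitDataset:
    """Seeded stratified partition into train/val/test.

    Per class, train gets floor(f_train * n_c) windows and val
    floor(f_val * n_c); the remainder goes to test.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    buckets: dict[str, list[SensorWindow]] = {"train": [], "val": [], "test": []}
    for class_id in sorted(dataset.class_names):
        wins = [w for w in dataset.windows if w.label == class_id]
        if not wins:
            continue
        n_c = len(wins)
        n_train = int(np.floor(fractions[0] * n_c))
        n_val = int(np.floor(fractions[1] * n_c))
        n_test = n_c - n_train - n_val
        if min(n_train, n_val, n_test) < 1:
            raise ValueError(
                f"class {dataset.class_names[class_id]!r} has {n_c} windows, "
                f"too few for a {fractions} split with >=1 window per partition"
            )
        perm = rng.permutation(n_c)
        buckets["train"] += [wins[i] for i in perm[:n_train]]
        buckets["val"] += [wins[i] for i in perm[n_train : n_train + n_val]]
        buckets["test"] += [wins[i] for i in perm[n_train + n_val :]]
    names = dict(dataset.class_names)
    prov = dict(dataset.provenance)
    return SplitDataset(
        train=LabeledDataset(buckets["train"], names, dict(prov, partition="train")),
        val=LabeledDataset(buckets["val"], names, dict(prov, partition="val")),
        test=LabeledDataset(buckets["test"], names, dict(prov, partition="test")),
        split_seed=seed,
    )


def _compute_stats(
    windows: list[SensorWindow], class_ids: list[int]
) -> ChannelStats:
    mu = np.zeros((len(class_ids), N_CHANNELS))
    sigma = np.zeros_like(mu)
    for r, cid in enumerate(class_ids):
        vals = [w.values for w in windows if w.label == cid]
        if not vals:
            raise DegenerateChannelError(f"no windows for class {cid}")
        stacked = np.concatenate(vals, axis=0)  # (sum NT, NC)
        mu[r] = stacked.mean(axis=0)
        sigma[r] = stacked.std(axis=0)  # population SD
        zero = np.where(sigma[r] == 0.0)[0]
        if zero.size:
            raise DegenerateChannelError(
                f"class {cid}: zero-variance channel(s) {zero.tolist()}"
            )
    return ChannelStats(class_ids=class_ids, mu=mu, sigma=sigma)


def _apply_stats(ds: LabeledDataset, stats: ChannelStats, invert: bool = False) -> LabeledDataset:
    wins = []
    for w in ds.windows:
        r = stats.row(w.label)
        if invert:
            vals = w.values * stats.sigma[r] + stats.mu[r]
        else:
            vals = (w.values - stats.mu[r]) / stats.sigma[r]
        wins.append(SensorWindow(vals, w.label, w.window_id))
    return LabeledDataset(wins, dict(ds.class_names), dict(ds.provenance))


def zscore_per_class(
    split: SplitDataset, train_only_stats: bool = False
) -> tuple[SplitDataset, ChannelStats]:
    """Standardize each (class, channel) to zero mean, unit variance.

    Statistics are computed over all data points of the class across
    the whole split (the study convention), or from the training
    partition only when ``train_only_stats`` is set.
    """
    class_ids = sorted(split.train.class_names)
    source = split.train.windows if train_only_stats else split.all_windows()
    stats = _compute_stats(source, class_ids)
    out = SplitDataset(
        train=_apply_stats(split.train, stats),
        val=_apply_stats(split.val, stats),
        test=_apply_stats(split.test, stats),
        split_seed=split.split_seed,
        stats=stats,
    )
    return out, stats


def unnormalize(ds: LabeledDataset, stats: ChannelStats) -> LabeledDataset:
    """Invert :func:`zscore_per_class` given the stored statistics."""
    return _apply_stats(ds, stats, invert=True)


def preprocess(
    dataset: LabeledDataset,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    train_only_stats: bool = False,
) -> tuple[SplitDataset, list[str]]:
    """Full chain: filter -> balance -> split -> per-class Z-score."""
    filtered, report = filter_zero_rows(dataset)
    balanced = balance_classes(filtered, seed=seed)
    split = split_dataset(balanced, fractions=fractions, seed=seed)
    normalized, _ = zscore_per_class(split, train_only_stats=train_only_stats)
    return normalized, report
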