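"""Evaluation protocols: paired splits, learning curves, size sweeps,
balanced-subsample training.

The two ordered observations of an unordered coculture pair — ``X_ij`` and
``X_ji`` — come from the same physical experiment, so every train/test split
keeps them on the same side (the pairing constraint).  Learning curves
report the *median* balanced accuracy over repeated paired splits at each
training fraction; the community-size sweep repeats the whole curve on
random organism subsets.  Balanced-subsample training handles a rare class
by pairing every rare sample with an equally sized draw from the majority.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import (ForestModel, balanced_accuracy_from_labels, oob_votes,
                     train_forest)
from .traitspace import CompositeDataset

__all__ = [
    "LearningCurveResult",
    "paired_split",
    "learning_curve",
    "community_size_sweep",
    "balanced_subsample_train",
    "DEFAULT_FRACTIONS",
    "DEFAULT_COMMUNITY_SIZES",
]

DEFAULT_FRACTIONS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)
DEFAULT_COMMUNITY_SIZES = (10, 20, 30, 40, 50, 60, 70, 80, 90)

_MAX_REDRAWS = 100


def _unordered_pairs(dataset: CompositeDataset) -> list[frozenset]:
    seen: list[frozenset] = []
    found = set()
    for i, j in dataset.pairs:
        key = frozenset((i, j))
        if key not in found:
            found.add(key)
            seen.append(key)
    return seen


def paired_split(dataset: CompositeDataset, fraction: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split dataset rows into train/test at the unordered-pair level.

    A fraction of the unordered pairs goes to training; both ordered rows of
    a pair always land on the same side.  Returns row index arrays.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    pairs = _unordered_pairs(dataset)
    n_train = int(round(fraction * len(pairs)))
    if n_train < 1 or n_train >= len(pairs):
        raise ValueError(
            f"fraction {fraction} leaves an empty train or test side "
            f"({n_train} of {len(pairs)} pairs)")
    order = rng.permutation(len(pairs))
    train_keys = {pairs[k] for k in order[:n_train]}
    train_idx, test_idx = [], []
    for row, (i, j) in enumerate(dataset.pairs):
        (train_idx if frozenset((i, j)) in train_keys else test_idx).append(row)
    return np.asarray(train_idx), np.asarray(test_idx)


@dataclass(frozen=True)
class LearningCurveResult:
    """Balanced accuracies over paired train/test splits per training fraction."""

    fractions: tuple[float, ...]
    accuracies: tuple[tuple[float, ...], ...]  # per fraction, per repeat
    n_repeats: int
    seed: int
    community_size: int

    @property
    def medians(self) -> np.ndarray:
        return np.array([np.median(a) for a in self.accuracies])

    def to_rows(self):
        for f, accs in zip(self.fractions, self.accuracies):
            med = float(np.median(accs))
            for r, acc in enumerate(accs):
                yield {"fraction": f, "repeat": r, "balanced_accuracy": acc,
                       "median": med}


def learning_curve(dataset: CompositeDataset, fractions=DEFAULT_FRACTIONS,
                   n_repeats: int = 10, n_trees: int = 500,
                   m_try: int | None = None, seed: int = 0,
                   min_node: int = 1) -> LearningCurveResult:
    """Median held-out balanced accuracy as a function of training fraction.

    Each repeat draws a fresh paired split, trains a forest on the training
    side and scores balanced accuracy on the held-out side.  A split whose
    training side contains a single class is redrawn (up to 100 times).
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    organisms = {o for pair in dataset.pairs for o in pair}
    all_accs = []
    for fraction in fractions:
        accs = []
        for _ in range(n_repeats):
            for attempt in range(_MAX_REDRAWS):
                train_idx, test_idx = paired_split(dataset, fraction, rng)
                y_train = dataset.labels[train_idx]
                y_test = dataset.labels[test_idx]
                if (y_train.min() != y_train.max()
                        and y_test.min() != y_test.max()):
                    break
            else:
                raise RuntimeError(
                    f"could not draw a two-class split at fraction {fraction} "
                    f"after {_MAX_REDRAWS} attempts")
            model = train_forest(dataset.subset_rows(train_idx), n_trees,
                                 m_try, seed=int(rng.integers(2**31)),
                                 min_node=min_node)
            pred, _ = model.predict(dataset.design[test_idx])
            accs.append(balanced_accuracy_from_labels(y_test, pred))
        all_accs.append(tuple(accs))
    return LearningCurveResult(tuple(fractions), tuple(all_accs), n_repeats,
                               seed, len(organisms))


def community_size_sweep(dataset: CompositeDataset, sizes=None,
                         n_communities: int = 5, fractions=DEFAULT_FRACTIONS,
                         n_repeats: int = 10, n_trees: int = 500,
                         m_try: int | None = None, seed: int = 0) -> dict:
    """Median learning curves for random organism subsets of each size.

    For each community size, ``n_communities`` organism subsets are drawn
    independently (subsets of different draws may overlap) and a learning
    curve computed on the induced sub-dataset; the per-size result is the
    median across communities of the per-fraction medians.
    Returns ``{size: (median_curve, [LearningCurveResult, ...])}``.
    """
    organisms = sorted({o for pair in dataset.pairs for o in pair})
    if sizes is None:
        sizes = [c for c in DEFAULT_COMMUNITY_SIZES if c <= len(organisms)]
    rng = np.random.default_rng(seed)
    out = {}
    for size in sizes:
        if size > len(organisms):
            raise ValueError(
                f"community size {size} exceeds the {len(organisms)} organisms")
        curves = []
        for _ in range(n_communities):
            subset = [organisms[k] for k in
                      rng.choice(len(organisms), size=size, replace=False)]
            sub = dataset.subset_organisms(subset)
            curves.append(learning_curve(sub, fractions, n_repeats, n_trees,
                                         m_try, seed=int(rng.integers(2**31))))
        median_curve = np.median(np.vstack([c.medians for c in curves]), axis=0)
        out[size] = (median_curve, curves)
    return out


@dataclass(frozen=True)
class BalancedSubsampleResult:
    accuracies: tuple[float, ...]
    median: float
    models: tuple


def balanced_subsample_train(dataset: CompositeDataset, rare_class: int,
                             n_repeats: int = 100, n_trees: int = 500,
                             m_try: int | None = None, seed: int = 0,
                             keep_models: bool = False) -> BalancedSubsampleResult:
    """Repeatedly train on balanced subsamples of a skewed dataset.

    Every repeat keeps all rare-class rows and draws an equal number of
    majority rows without replacement, trains a forest, and records its
    out-of-bag balanced accuracy.  Reports per-repeat accuracies and the
    median (optionally the models themselves).
    """
    y = dataset.labels
    if rare_class not in (0, 1):
        raise ValueError("rare_class must be 0 or 1")
    rare_idx = np.nonzero(y == rare_class)[0]
    major_idx = np.nonzero(y != rare_class)[0]
    if len(rare_idx) == 0 or len(major_idx) == 0:
        raise ValueError("both classes must be present")
    if len(rare_idx) > len(major_idx):
        raise ValueError(
            f"class {rare_class} has {len(rare_idx)} samples but the other "
            f"class only {len(major_idx)}; it is not the rare class")
    rng = np.random.default_rng(seed)
    accs, models = [], []
    for _ in range(n_repeats):
        draw = rng.choice(major_idx, size=len(rare_idx), replace=False)
        idx = np.sort(np.concatenate([rare_idx, draw]))
        sub = dataset.subset_rows(idx)
        model = train_forest(sub, n_trees, m_try,
                             seed=int(rng.integers(2**31)))
        votes = oob_votes(model, sub)
        mask = votes.counted_mask()
        accs.append(balanced_accuracy_from_labels(
            sub.labels[mask], votes.predicted[mask]))
        if keep_models:
            models.append(model)
    return BalancedSubsampleResult(tuple(accs), float(np.median(accs)),
                                   tuple(models))
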