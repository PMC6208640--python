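"""From-scratch random forest for binary classification over binary traits.

The forest keeps everything the downstream mechanism-ranking analysis needs
and that off-the-shelf implementations discard: per-node class counts at
every node of every tree, and per-tree bootstrap (in-bag) membership, so
out-of-bag votes and per-sample feature contributions can be replayed
exactly.  Features are strictly binary, so every split is "value 0 goes
left, value 1 goes right" and no threshold search is needed.

Conventions fixed here and relied on elsewhere:

* class 1 is the positive class; a tree votes positive at a leaf only when
  strictly more in-bag positives than negatives reached it;
* a forest vote fraction of exactly 0.5 resolves to the negative class;
* equal-gain split candidates resolve to the lowest feature index;
* one seed expands to an independent RNG stream per tree, so growing a
  larger forest never reshuffles the earlier trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .traitspace import CompositeDataset, RocCurve, roc_curve_from_scores

__all__ = [
    "DecisionTree",
    "ForestModel",
    "VoteSummary",
    "gini_impurity",
    "grow_tree",
    "train_forest",
    "oob_votes",
    "balanced_accuracy",
    "roc_auc",
    "permutation_importance",
    "save_model",
    "load_model",
]

SERIALIZATION_VERSION = 1


def gini_impurity(class_counts) -> float:
    """Gini impurity ``1 - p0^2 - p1^2`` of a two-class count pair."""
    c0, c1 = class_counts
    total = c0 + c1
    if total <= 0:
        raise ValueError("Gini impurity undefined for an empty node")
    p0 = c0 / total
    p1 = c1 / total
    return 1.0 - p0 * p0 - p1 * p1


@dataclass
class DecisionTree:
    """Flat array representation of one grown tree.

    ``feature[k] == -1`` marks a leaf; otherwise ``left[k]``/``right[k]``
    are the child node ids for feature value 0/1.  ``counts[k]`` are the
    (negative, positive) in-bag class counts of node ``k``; children
    partition their parent's counts exactly.  ``in_bag_count[s]`` is the
    number of times training sample ``s`` was drawn into this tree's
    bootstrap (0 means the sample is out-of-bag for this tree).
    """

    feature: np.ndarray      # int32 (n_nodes,)
    left: np.ndarray         # int32 (n_nodes,)
    right: np.ndarray        # int32 (n_nodes,)
    counts: np.ndarray       # int64 (n_nodes, 2)
    in_bag_count: np.ndarray  # int32 (n_train,)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def oob_mask(self) -> np.ndarray:
        return self.in_bag_count == 0

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for every row of ``X`` (vectorized descent)."""
        X = np.atleast_2d(X)
        node = np.zeros(len(X), dtype=np.int32)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.nonzero(active)[0]
            nd = node[idx]
            f = self.feature[nd]
            vals = X[idx, f]
            node[idx] = np.where(vals == 0, self.left[nd], self.right[nd])
            active[idx] = self.feature[node[idx]] >= 0
        return node

    def votes(self, X: np.ndarray) -> np.ndarray:
        """Per-row class vote (1 iff the leaf holds a strict positive majority)."""
        leaves = self.apply(X)
        c = self.counts[leaves]
        return (c[:, 1] > c[:, 0]).astype(np.int8)

    def used_features(self) -> np.ndarray:
        f = self.feature[self.feature >= 0]
        return np.unique(f)

    def positive_fraction(self, node: int) -> float:
        c0, c1 = self.counts[node]
        return c1 / (c0 + c1)


def grow_tree(design: np.ndarray, labels: np.ndarray, in_bag_ids: np.ndarray,
              m_try: int, rng: np.random.Generator, min_node: int = 1) -> DecisionTree:
    """Grow one CART-style tree on the bootstrap sample ``in_bag_ids``.

    At each node a fresh draw of ``m_try`` features (without replacement) is
    scored by Gini impurity decrease; growth stops when a node is pure,
    holds fewer than ``min_node`` samples, or no sampled split reduces
    impurity.
    """
    design = np.asarray(design, dtype=np.int8)
    labels = np.asarray(labels, dtype=np.int8)
    in_bag_ids = np.asarray(in_bag_ids, dtype=np.int64)
    if len(in_bag_ids) == 0:
        raise ValueError("cannot grow a tree on an empty in-bag set")
    n_features = design.shape[1]
    if not 1 <= m_try <= n_features:
        raise ValueError(f"m_try must be in [1, {n_features}], got {m_try}")
    if min_node < 1:
        raise ValueError("min_node must be >= 1")

    Xb = design[in_bag_ids]
    yb = labels[in_bag_ids]

    feature: list[int] = []
    left: list[int] = []
    right: list[int] = []
    counts: list[tuple[int, int]] = []

    def new_node(n0: int, n1: int) -> int:
        feature.append(-1)
        left.append(-1)
        right.append(-1)
        counts.append((n0, n1))
        return len(feature) - 1

    def build(row_idx: np.ndarray) -> int:
        n1 = int(yb[row_idx].sum())
        n0 = len(row_idx) - n1
        node = new_node(n0, n1)
        if n0 == 0 or n1 == 0 or len(row_idx) < min_node:
            return node
        cand = np.sort(rng.choice(n_features, size=m_try, replace=False))
        Xs = Xb[row_idx][:, cand].astype(np.int64)
        tot1 = Xs.sum(axis=0)                        # samples with feature = 1
        pos1 = yb[row_idx].astype(np.int64) @ Xs     # positives with feature = 1
        tot0 = len(row_idx) - tot1
        pos0 = n1 - pos1
        valid = (tot0 > 0) & (tot1 > 0)
        if not valid.any():
            return node
        with np.errstate(divide="ignore", invalid="ignore"):
            g0 = 1.0 - (pos0 / tot0) ** 2 - ((tot0 - pos0) / tot0) ** 2
            g1 = 1.0 - (pos1 / tot1) ** 2 - ((tot1 - pos1) / tot1) ** 2
        child = (tot0 * g0 + tot1 * g1) / len(row_idx)
        parent = gini_impurity((n0, n1))
        decrease = np.where(valid, parent - child, -np.inf)
        best = int(np.argmax(decrease))  # cand is sorted: first max = lowest index
        if decrease[best] <= 1e-15:
            return node
        f = int(cand[best])
        mask = Xb[row_idx, f] == 1
        l_id = build(row_idx[~mask])
        r_id = build(row_idx[mask])
        feature[node] = f
        left[node] = l_id
        right[node] = r_id
        return node

    build(np.arange(len(in_bag_ids)))
    in_bag_count = np.bincount(in_bag_ids, minlength=len(design)).astype(np.int32)
    return DecisionTree(
        np.asarray(feature, dtype=np.int32), np.asarray(left, dtype=np.int32),
        np.asarray(right, dtype=np.int32), np.asarray(counts, dtype=np.int64),
        in_bag_count)


@dataclass
class ForestModel:
    """Trained ensemble with bootstrap bookkeeping."""

    trees: list[DecisionTree]
    m_try: int
    feature_names: tuple[str, ...]
    class_names: tuple[str, str]   # (negative, positive)
    seed: int
    min_node: int = 1
    n_train: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.int8))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"composite vector length {X.shape[1]} does not match the "
                f"{self.n_features} model features")
        return X

    def vote_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_trees) matrix of per-tree class votes."""
        X = self._check_width(X)
        return np.column_stack([t.votes(X) for t in self.trees])

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Majority vote over all trees.

        Returns ``(classes, positive_vote_fractions)``; a fraction of
        exactly 0.5 resolves to the negative class.
        """
        votes = self.vote_matrix(X)
        frac = votes.mean(axis=1)
        return (frac > 0.5).astype(np.int8), frac

    def predict_one(self, x: np.ndarray) -> tuple[int, float]:
        classes, frac = self.predict(np.atleast_2d(x))
        return int(classes[0]), float(frac[0])


def _default_m_try(n_features: int) -> int:
    return max(1, int(np.floor(np.sqrt(n_features))))


def tree_rngs(seed: int, n_trees: int) -> list[np.random.Generator]:
    """One independent child stream per tree from a single seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(n_trees)]


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], tuple[str, str]]:
    if isinstance(dataset, CompositeDataset):
        return (dataset.design, dataset.labels, dataset.feature_names,
                dataset.class_names)
    X, y = dataset
    X = np.asarray(X, dtype=np.int8)
    y = np.asarray(y, dtype=np.int8)
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return X, y, names, ("0", "1")


def train_forest(dataset, n_trees: int = 500, m_try: int | None = None,
                 seed: int = 0, min_node: int = 1) -> ForestModel:
    """Train ``n_trees`` independent bootstrap trees.

    ``dataset`` is a :class:`CompositeDataset` or an ``(X, y)`` pair.  Each
    tree draws its own bootstrap of the full training set (sampling rows
    with replacement) and grows with ``m_try`` candidate features per split
    (default ``floor(sqrt(n_features))``).  Fully reproducible given
    ``seed``.
    """
    X, y, feature_names, class_names = _as_xy(dataset)
    if len(X) < 2:
        raise ValueError("training needs at least two samples")
    if y.min() == y.max():
        raise ValueError(
            f"training set contains a single class "
            f"({class_names[int(y[0])]}); both classes are required")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if m_try is None:
        m_try = _default_m_try(X.shape[1])
    n = len(X)
    trees = []
    for rng in tree_rngs(seed, n_trees):
        in_bag = rng.integers(0, n, size=n)
        trees.append(grow_tree(X, y, in_bag, m_try, rng, min_node))
    return ForestModel(trees, m_try, feature_names, class_names, seed,
                       min_node, n)


@dataclass
class VoteSummary:
    """Per-sample vote fractions over the counted trees.

    In ``oob`` mode only trees for which a sample is out-of-bag are counted;
    a sample that is in-bag for every tree has ``counted == 0`` and a NaN
    fraction (flagged, not an error).
    """

    fraction: np.ndarray   # positive-class vote fraction, NaN if uncounted
    counted: np.ndarray    # number of trees counted per sample
    predicted: np.ndarray  # class by the 0.5 tie rule, -1 if uncounted
    mode: str              # {"oob", "all_trees"}

    def counted_mask(self) -> np.ndarray:
        return self.counted > 0


def oob_votes(model: ForestModel, dataset) -> VoteSummary:
    """Out-of-bag vote summary on the training set."""
    X, y, _, _ = _as_xy(dataset)
    if len(X) != model.n_train:
        raise ValueError(
            f"out-of-bag votes need the training set of {model.n_train} samples, "
            f"got {len(X)}")
    votes = model.vote_matrix(X)
    oob = np.column_stack([t.oob_mask() for t in model.trees])
    counted = oob.sum(axis=1)
    pos = (votes * oob).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(counted > 0, pos / np.maximum(counted, 1), np.nan)
    predicted = np.where(counted > 0, (frac > 0.5).astype(np.int8), -1)
    return VoteSummary(frac, counted, predicted.astype(np.int8), "oob")


def all_tree_votes(model: ForestModel, dataset) -> VoteSummary:
    if isinstance(dataset, CompositeDataset):
        X = dataset.design
    else:
        X = np.atleast_2d(np.asarray(dataset, dtype=np.int8))
    votes = model.vote_matrix(X)
    frac = votes.mean(axis=1)
    counted = np.full(len(frac), model.n_trees)
    return VoteSummary(frac, counted, (frac > 0.5).astype(np.int8), "all_trees")


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """``[TP/(TP+FN) + TN/(TN+FP)] / 2`` — mean of sensitivity and specificity."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("balanced accuracy needs at least one sample of each class")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def balanced_accuracy_from_labels(y_true, y_pred) -> float:
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred != 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred != 0)))
    return balanced_accuracy(tp, fn, tn, fp)


def roc_auc(votes, labels) -> RocCurve:
    """ROC over the positive-vote fraction as the classification threshold.

    Accepts a :class:`VoteSummary` (uncounted samples are dropped) or a raw
    score vector.
    """
    if isinstance(votes, VoteSummary):
        mask = votes.counted_mask()
        scores = votes.fraction[mask]
        labels = np.asarray(labels)[mask]
    else:
        scores = np.asarray(votes, dtype=float)
        labels = np.asarray(labels)
    return roc_curve_from_scores(scores, labels)


def permutation_importance(model: ForestModel, dataset, seed: int = 0) -> np.ndarray:
    """Mean decrease in accuracy per feature (out-of-bag permutation).

    For each tree and each feature the tree actually splits on, the tree's
    accuracy on its out-of-bag samples is compared with the accuracy after
    permuting that feature's values among those samples; the decreases are
    averaged over all trees.  Features used by no tree score exactly 0.
    """
    X, y, _, _ = _as_xy(dataset)
    if len(X) != model.n_train:
        raise ValueError("permutation importance needs the training set")
    importance = np.zeros(model.n_features)
    for t, rng in zip(model.trees, tree_rngs(seed, model.n_trees)):
        mask = t.oob_mask()
        if not mask.any():
            continue
        Xo = X[mask]
        yo = y[mask]
        base = float(np.mean(t.votes(Xo) == yo))
        for f in t.used_features():
            Xp = Xo.copy()
            Xp[:, f] = Xo[rng.permutation(len(Xo)), f]
            perm = float(np.mean(t.votes(Xp) == yo))
            importance[f] += base - perm
    return importance / model.n_trees


# ---------------------------------------------------------------------------
# serialization (versioned JSON; round-trips bit-exactly)

def model_to_dict(model: ForestModel) -> dict:
    return {
        "format": "traitforest-model",
        "version": SERIALIZATION_VERSION,
        "n_trees": model.n_trees,
        "m_try": model.m_try,
        "min_node": model.min_node,
        "seed": model.seed,
        "n_train": model.n_train,
        "class_names": list(model.class_names),
        "feature_names": list(model.feature_names),
        "trees": [
            {
                "node_id": list(range(t.n_nodes)),
                "split_feature": [
                    None if f < 0 else model.feature_names[f] for f in t.feature],
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "class_counts": t.counts.tolist(),
                "in_bag_count": t.in_bag_count.tolist(),
            }
            for t in model.trees
        ],
    }


def model_from_dict(payload: dict) -> ForestModel:
    if payload.get("format") != "traitforest-model":
        raise ValueError("not a traitforest model file")
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')}")
    feature_names = tuple(payload["feature_names"])
    index = {name: i for i, name in enumerate(feature_names)}
    trees = []
    for td in payload["trees"]:
        feature = np.array(
            [-1 if f is None else index[f] for f in td["split_feature"]],
            dtype=np.int32)
        trees.append(DecisionTree(
            feature,
            np.asarray(td["left"], dtype=np.int32),
            np.asarray(td["right"], dtype=np.int32),
            np.asarray(td["class_counts"], dtype=np.int64),
            np.asarray(td["in_bag_count"], dtype=np.int32)))
    return ForestModel(trees, payload["m_try"], feature_names,
                       tuple(payload["class_names"]), payload["seed"],
                       payload["min_node"], payload["n_train"])


def save_model(model: ForestModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> ForestModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
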