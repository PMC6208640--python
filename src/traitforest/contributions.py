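"""Per-sample feature contributions and mechanism ranking.

A trained forest classifies a coculture sample, but the interesting question
is *why*: which trait (e.g. which exchanged metabolite) drove the call?
Following the decision-path decomposition used for tree ensembles
(forestFloor / treeinterpreter style), each node on a sample's root-to-leaf
path that splits on feature ``f`` contributes the local increment
``Y_child - Y_node`` to ``phi_f``, where ``Y`` is the positive-class
fraction of in-bag training samples at the node.  Averaged over the counted
trees (the out-of-bag trees for a training sample, all trees for a new
sample) this yields an exactly additive decomposition::

    baseline + sum_f phi_f == mean leaf positive fraction over counted trees

To rank candidate interaction mechanisms, each candidate metabolite maps to
one responder-half and one partner-half feature; their contributions are
summed into a *net contribution* and the candidates sorted.  Competitive
mechanisms (which push toward the negative class) are read from the negative
end, facilitative ones from the positive end.  The analytic random-query
baseline ``(n_candidates + 1) / (n_true + 1)`` says how many candidates a
uniformly random investigation order would need on average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forest import DecisionTree, ForestModel

__all__ = [
    "ContributionVector",
    "MechanismRanking",
    "path_increments",
    "feature_contributions",
    "net_contributions",
    "first_true_rank",
    "expected_random_rank",
    "query_count_evaluation",
]


def path_increments(tree: DecisionTree, composite: np.ndarray) -> np.ndarray:
    """Per-feature local increments along one sample's path in one tree.

    The increments telescope: their sum equals ``Y_leaf - Y_root``.
    """
    x = np.asarray(composite).ravel()
    if tree.counts.shape[0] != tree.n_nodes or tree.counts.shape[1] != 2:
        raise ValueError("tree is missing per-node class counts")
    inc = np.zeros(len(x))
    node = 0
    while tree.feature[node] >= 0:
        f = tree.feature[node]
        if f >= len(x):
            raise ValueError(
                f"composite vector of length {len(x)} too short for split feature {f}")
        child = tree.right[node] if x[f] == 1 else tree.left[node]
        inc[f] += tree.positive_fraction(child) - tree.positive_fraction(node)
        node = child
    return inc


@dataclass(frozen=True)
class ContributionVector:
    """Additive decomposition of one sample's forest score."""

    sample_id: object
    phi: np.ndarray          # per-feature contribution, length n_features
    baseline: float          # mean root positive fraction over counted trees
    counted_trees: int
    mode: str                # {"oob", "all_trees"}
    denominator: str = "counted"

    @property
    def total(self) -> float:
        return float(self.baseline + self.phi.sum())


def feature_contributions(model: ForestModel, composite: np.ndarray,
                          train_id: int | None = None, mode: str = "oob",
                          denominator: str = "counted") -> ContributionVector:
    """Average the path increments of one sample over the counted trees.

    For a training sample (``mode="oob"``, ``train_id`` given) only trees
    for which the sample is out-of-bag are counted; for a new sample use
    ``mode="all_trees"``.  ``denominator="counted"`` divides by the number
    of counted trees (keeps the decomposition exactly additive);
    ``"total"`` divides by the full forest size instead, as a sensitivity
    variant.
    """
    if mode not in ("oob", "all_trees"):
        raise ValueError(f"mode must be 'oob' or 'all_trees', got {mode!r}")
    if denominator not in ("counted", "total"):
        raise ValueError(f"denominator must be 'counted' or 'total', got {denominator!r}")
    x = np.asarray(composite).ravel()
    if len(x) != model.n_features:
        raise ValueError(
            f"composite vector length {len(x)} does not match the "
            f"{model.n_features} model features")
    if mode == "oob":
        if train_id is None:
            raise ValueError("oob mode needs the sample's training id")
        trees = [t for t in model.trees if t.in_bag_count[train_id] == 0]
        if not trees:
            raise ValueError(
                f"training sample {train_id} is in-bag for every tree; "
                "no out-of-bag trees to evaluate")
    else:
        trees = model.trees
    phi = np.zeros(model.n_features)
    root_sum = 0.0
    for t in trees:
        phi += path_increments(t, x)
        root_sum += t.positive_fraction(0)
    denom = len(trees) if denominator == "counted" else model.n_trees
    return ContributionVector(train_id, phi / denom, root_sum / len(trees),
                              len(trees), mode, denominator)


@dataclass(frozen=True)
class MechanismRanking:
    """Candidates sorted by net contribution.

    ``direction="from_negative_end"`` reads the most negative net first
    (mechanisms of negative-class outcomes, e.g. contended metabolites);
    ``"from_positive_end"`` reads the most positive first (facilitative
    metabolites).  Ties order alphabetically by candidate name.
    ``zero_presence`` flags candidates whose mapped features are 0 in both
    halves of the sample's composite vector (the candidate is absent from
    both organisms; its rank is reported but carries no trait support).
    """

    candidates: tuple[str, ...]
    net: dict[str, float]
    direction: str
    zero_presence: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.direction not in ("from_negative_end", "from_positive_end"):
            raise ValueError(f"unknown ranking direction {self.direction!r}")

    def ordered(self) -> list[str]:
        sign = 1.0 if self.direction == "from_negative_end" else -1.0
        return sorted(self.candidates, key=lambda c: (sign * self.net[c], c))

    def rank_of(self, candidate: str) -> int:
        return self.ordered().index(candidate) + 1


def net_contributions(contrib: ContributionVector, candidate_map: dict,
                      feature_names, direction: str = "from_negative_end",
                      composite: np.ndarray | None = None) -> MechanismRanking:
    """Sum responder- and partner-half contributions per candidate and sort.

    ``candidate_map`` maps each candidate name to a
    ``(responder_feature, partner_feature)`` pair of feature names; the two
    halves of the composite vector describe the same underlying trait seen
    from the responder and from the partner, and their contributions add up
    to the candidate's net score.
    """
    index = {name: i for i, name in enumerate(feature_names)}
    seen: dict[str, str] = {}
    net: dict[str, float] = {}
    zero = set()
    for cand, (f_resp, f_part) in candidate_map.items():
        for f in (f_resp, f_part):
            if f in seen:
                raise ValueError(
                    f"feature {f!r} mapped to both {seen[f]!r} and {cand!r}")
            seen[f] = cand
            if f not in index:
                raise ValueError(f"unknown feature {f!r} for candidate {cand!r}")
        net[cand] = float(contrib.phi[index[f_resp]] + contrib.phi[index[f_part]])
        if composite is not None:
            x = np.asarray(composite).ravel()
            if x[index[f_resp]] == 0 and x[index[f_part]] == 0:
                zero.add(cand)
    return MechanismRanking(tuple(candidate_map), net, direction, frozenset(zero))


def first_true_rank(ranking: MechanismRanking, truth) -> int:
    """1-based position of the first true candidate in the reading order."""
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    unknown = truth - set(ranking.candidates)
    if unknown:
        raise ValueError(f"truth candidates not in ranking: {sorted(unknown)}")
    for pos, cand in enumerate(ranking.ordered(), start=1):
        if cand in truth:
            return pos
    raise AssertionError("unreachable: truth is a subset of candidates")


def expected_random_rank(n_candidates: int, n_true: int) -> float:
    """Expected 1-based position of the first true candidate under uniformly
    random querying without replacement: ``(n_candidates + 1) / (n_true + 1)``.
    """
    if not 1 <= n_true <= n_candidates:
        raise ValueError(
            f"need 1 <= n_true <= n_candidates, got n_true={n_true}, "
            f"n_candidates={n_candidates}")
    return (n_candidates + 1) / (n_true + 1)


def monte_carlo_random_rank(n_candidates: int, n_true: int, n_shuffles: int,
                            rng: np.random.Generator) -> float:
    """Simulation cross-check of :func:`expected_random_rank`."""
    if not 1 <= n_true <= n_candidates:
        raise ValueError("need 1 <= n_true <= n_candidates")
    # position of the first of n_true marked items in a random permutation
    ranks = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(n_candidates)
        ranks[k] = np.nonzero(perm < n_true)[0][0] + 1
    return float(ranks.mean())


@dataclass(frozen=True)
class QueryCountSummary:
    """Distribution of first-true ranks vs the analytic random baseline."""

    sample_pairs: tuple
    ranks: np.ndarray
    random_baseline: np.ndarray  # expected random rank per sample
    skipped: tuple               # pairs without ground truth

    @property
    def median_rank(self) -> float:
        return float(np.median(self.ranks))

    @property
    def mean_rank(self) -> float:
        return float(np.mean(self.ranks))

    @property
    def median_random(self) -> float:
        return float(np.median(self.random_baseline))

    @property
    def mean_random(self) -> float:
        return float(np.mean(self.random_baseline))


def query_count_evaluation(model: ForestModel, dataset, truths: dict,
                           candidate_map: dict,
                           direction_by_class: dict | None = None,
                           mode: str = "oob",
                           sample_ids=None) -> QueryCountSummary:
    """Rank mechanisms for every sample with ground truth and summarize.

    ``truths`` maps an ordered pair ``(responder, partner)`` to its set of
    true mechanism candidates.  The reading direction follows the sample's
    class: negative-class samples are read from the negative end
    (competition), positive-class from the positive end (facilitation),
    unless overridden via ``direction_by_class``.  Samples with an empty or
    missing truth set are skipped and reported, not failed.
    """
    if direction_by_class is None:
        direction_by_class = {0: "from_negative_end", 1: "from_positive_end"}
    if sample_ids is None:
        sample_ids = range(dataset.n_samples)
    n_cand = len(candidate_map)
    pairs, ranks, baseline, skipped = [], [], [], []
    for sid in sample_ids:
        pair = dataset.pairs[sid]
        truth = truths.get(pair)
        if not truth:
            skipped.append(pair)
            continue
        x = dataset.design[sid]
        contrib = feature_contributions(
            model, x, train_id=sid if mode == "oob" else None, mode=mode)
        direction = direction_by_class[int(dataset.labels[sid])]
        ranking = net_contributions(contrib, candidate_map,
                                    dataset.feature_names, direction, x)
        pairs.append(pair)
        ranks.append(first_true_rank(ranking, truth))
        baseline.append(expected_random_rank(n_cand, len(truth)))
    return QueryCountSummary(tuple(pairs), np.asarray(ranks, dtype=float),
                             np.asarray(baseline, dtype=float), tuple(skipped))
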