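"""Binary trait matrices, interaction tables and composite pair datasets.

Each organism ``i`` carries an ``n``-long binary trait vector ``F_i`` (presence
or absence of exchange reactions, biosynthetic capabilities, functional
modules).  A coculture observation of organism ``i`` responding to partner
``j`` is represented by the ordered composite vector ``[F_i, F_j]`` of length
``2n`` — responder first, so ``(i, j)`` and ``(j, i)`` are distinct samples —
together with a scalar response ``X_ij`` (relative yield, fold change, or a
binary survival flag).  This module reads and validates the on-disk tables,
assembles labelled composite datasets, and provides scalar-score baseline
classifiers (Jaccard distance, single-score threshold ROC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitMatrix",
    "InteractionTable",
    "CompositeDataset",
    "LabelRule",
    "RocCurve",
    "load_trait_matrix",
    "load_interaction_table",
    "build_composite",
    "assemble_dataset",
    "relative_yield",
    "jaccard_distance",
    "score_threshold_roc",
]

RESPONSE_MODES = ("relative_yield", "fold_change", "survival", "raw")

#: suffix appended to partner-half feature names in reports and serialized
#: models, so "uptake_glc" (responder) and "uptake_glc_p" (partner) stay
#: distinguishable in importance and contribution tables.
PARTNER_SUFFIX = "_p"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(names: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValidationError(f"duplicate {what}: {name!r}")
        seen.add(name)


@dataclass(frozen=True)
class TraitMatrix:
    """Organisms x features table of 0/1 trait values."""

    organism_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_organisms, n_features), int8 in {0, 1}

    def __post_init__(self) -> None:
        object.__setattr__(self, "organism_ids", tuple(self.organism_ids))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        if len(self.feature_names) < 1:
            raise ValidationError("trait matrix needs at least one feature")
        _check_unique(self.organism_ids, "organism id")
        _check_unique(self.feature_names, "feature name")
        values = np.asarray(self.values)
        if values.shape != (len(self.organism_ids), len(self.feature_names)):
            raise ValidationError(
                f"trait values shape {values.shape} does not match "
                f"{len(self.organism_ids)} organisms x {len(self.feature_names)} features"
            )
        bad = (values != 0) & (values != 1)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary trait value {values[r, c]!r} for organism "
                f"{self.organism_ids[r]!r}, feature {self.feature_names[c]!r}"
            )
        object.__setattr__(self, "values", values.astype(np.int8))

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def row(self, organism_id: str) -> np.ndarray:
        return self.values[self.organism_ids.index(organism_id)]

    def subset(self, organism_ids: Iterable[str]) -> "TraitMatrix":
        ids = list(organism_ids)
        idx = [self.organism_ids.index(o) for o in ids]
        return TraitMatrix(tuple(ids), self.feature_names, self.values[idx])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=list(self.organism_ids),
                          columns=list(self.feature_names))
        df.to_csv(path, sep="\t", index_label="organism")

    @classmethod
    def from_tsv(cls, path) -> "TraitMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValidationError(f"non-numeric trait value in {path}: {exc}") from exc
        return cls(tuple(str(i) for i in df.index),
                   tuple(str(c) for c in df.columns), values)


def load_trait_matrix(path) -> TraitMatrix:
    """Read a TSV with an ``organism`` id column and 0/1 feature columns."""
    return TraitMatrix.from_tsv(path)


@dataclass(frozen=True)
class InteractionTable:
    """Square response matrix; entry ``[i, j]`` is the response of organism
    ``i`` cocultured with partner ``j``.

    In ``relative_yield`` mode the diagonal holds the monoculture biomass
    ``B_ii`` (the reference the off-diagonal relative yields were computed
    against); in other modes the diagonal is ignored.  ``NaN`` marks pairs
    that were not measured.
    """

    organism_ids: tuple[str, ...]
    responses: np.ndarray  # (N, N) float, NaN = not measured
    response_mode: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "organism_ids", tuple(self.organism_ids))
        _check_unique(self.organism_ids, "organism id")
        if self.response_mode not in RESPONSE_MODES:
            raise ValidationError(
                f"response_mode must be one of {RESPONSE_MODES}, got {self.response_mode!r}")
        resp = np.asarray(self.responses, dtype=float)
        n = len(self.organism_ids)
        if resp.shape != (n, n):
            raise ValidationError(f"responses must be {n}x{n}, got {resp.shape}")
        object.__setattr__(self, "responses", resp)

    def response(self, i: str, j: str) -> float:
        a = self.organism_ids.index(i)
        b = self.organism_ids.index(j)
        return float(self.responses[a, b])

    def measured_pairs(self) -> list[tuple[str, str]]:
        """Ordered off-diagonal pairs with a recorded (non-NaN) response."""
        out = []
        for a, i in enumerate(self.organism_ids):
            for b, j in enumerate(self.organism_ids):
                if a != b and np.isfinite(self.responses[a, b]):
                    out.append((i, j))
        return out

    def subset(self, organism_ids: Iterable[str]) -> "InteractionTable":
        ids = list(organism_ids)
        idx = [self.organism_ids.index(o) for o in ids]
        return InteractionTable(tuple(ids), self.responses[np.ix_(idx, idx)],
                                self.response_mode)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.responses, index=list(self.organism_ids),
                          columns=list(self.organism_ids))
        df.to_csv(path, sep="\t", index_label="organism", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, response_mode: str = "raw") -> "InteractionTable":
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        if list(df.index) != list(df.columns):
            raise ValidationError(
                "interaction table must be square with identical row and column ids")
        return cls(tuple(str(i) for i in df.index), df.to_numpy(dtype=float),
                   response_mode)


def load_interaction_table(path, response_mode: str = "raw") -> InteractionTable:
    return InteractionTable.from_tsv(path, response_mode)


def relative_yield(b_coculture: float, b_monoculture: float) -> float:
    """Normalized biomass change of a responder in coculture.

    ``(B_ij - B_ii) / B_ii``: negative means the partner is detrimental,
    zero means no effect, positive means the partner is beneficial.
    """
    if b_monoculture <= 0:
        raise ValueError(
            f"monoculture biomass must be positive, got {b_monoculture}; "
            "relative yield is undefined when the monoculture failed")
    return (b_coculture - b_monoculture) / b_monoculture


@dataclass(frozen=True)
class LabelRule:
    """Maps a numeric response to one of two classes.

    mode ``sign``
        negative response -> negative class; response >= -tolerance
        (i.e. zero and positive) -> the "nonnegative" positive class.
    mode ``cutoff``
        response > cutoff -> "strong" positive class, else "weak"
        (a response exactly at the cutoff counts as weak).
    mode ``binary``
        response is already 0/1 and passes through.
    """

    mode: str = "sign"
    cutoff: float = 0.0
    tolerance: float = 0.0
    class_names: tuple[str, str] = None  # (negative_class, positive_class)

    def __post_init__(self) -> None:
        if self.mode not in ("sign", "cutoff", "binary"):
            raise ValidationError(f"unknown label rule mode {self.mode!r}")
        if self.class_names is None:
            default = {
                "sign": ("negative", "nonnegative"),
                "cutoff": ("weak", "strong"),
                "binary": ("0", "1"),
            }[self.mode]
            object.__setattr__(self, "class_names", default)
        else:
            object.__setattr__(self, "class_names", tuple(self.class_names))

    def classify(self, x: float) -> int:
        """Return 1 for the positive class, 0 for the negative class."""
        if not np.isfinite(x):
            raise ValueError(f"cannot classify non-finite response {x}")
        if self.mode == "sign":
            return int(x >= -self.tolerance)
        if self.mode == "cutoff":
            return int(x > self.cutoff)
        if x not in (0, 1):
            raise ValidationError(f"binary rule expects 0/1 responses, got {x}")
        return int(x)

    def describe(self) -> str:
        if self.mode == "sign":
            return (f"sign: {self.class_names[1]} if X >= {-self.tolerance}, "
                    f"else {self.class_names[0]}")
        if self.mode == "cutoff":
            return (f"cutoff {self.cutoff}: {self.class_names[1]} if X > "
                    f"{self.cutoff}, else {self.class_names[0]}")
        return f"binary passthrough ({self.class_names[0]}/{self.class_names[1]})"

    @classmethod
    def from_dict(cls, cfg: dict) -> "LabelRule":
        mode = cfg.get("mode", "sign")
        kwargs = {}
        if "cutoff" in cfg and cfg["cutoff"] is not None:
            kwargs["cutoff"] = float(cfg["cutoff"])
        if "tolerance" in cfg and cfg["tolerance"] is not None:
            kwargs["tolerance"] = float(cfg["tolerance"])
        if cfg.get("class_names"):
            kwargs["class_names"] = tuple(cfg["class_names"])
        return cls(mode=mode, **kwargs)


def build_composite(f_i: np.ndarray, f_j: np.ndarray) -> np.ndarray:
    """Concatenate responder and partner trait vectors, responder first."""
    f_i = np.asarray(f_i)
    f_j = np.asarray(f_j)
    if f_i.shape != f_j.shape or f_i.ndim != 1:
        raise ValueError(
            f"trait vectors must be 1-D and equal length, got {f_i.shape} and {f_j.shape}")
    return np.concatenate([f_i, f_j]).astype(np.int8)


@dataclass(frozen=True)
class CompositeDataset:
    """Labelled design matrix of ordered composite pair vectors.

    Row ``k`` is ``[F_i, F_j]`` for ``pairs[k] == (i, j)``; positions
    ``0..n-1`` hold the responder's traits.  ``labels`` is 1 for the
    positive class of ``rule`` and 0 otherwise.
    """

    pairs: tuple[tuple[str, str], ...]
    design: np.ndarray            # (n_samples, 2n) int8
    labels: np.ndarray            # (n_samples,) int8 in {0, 1}
    feature_names: tuple[str, ...]  # length 2n, partner half suffixed
    class_names: tuple[str, str]    # (negative, positive)
    label_rule: str = ""
    responses: np.ndarray = None    # raw numeric responses, same order

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple((str(a), str(b)) for a, b in self.pairs))
        design = np.asarray(self.design, dtype=np.int8)
        labels = np.asarray(self.labels, dtype=np.int8)
        if design.shape[0] != len(self.pairs) or labels.shape[0] != len(self.pairs):
            raise ValidationError("pairs, design and labels must align")
        for i, j in self.pairs:
            if i == j:
                raise ValidationError(f"diagonal pair ({i}, {i}) is not a coculture sample")
        object.__setattr__(self, "design", design)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "class_names", tuple(self.class_names))
        if self.responses is not None:
            object.__setattr__(self, "responses",
                               np.asarray(self.responses, dtype=float))

    @property
    def n_samples(self) -> int:
        return len(self.pairs)

    @property
    def n_features(self) -> int:
        return self.design.shape[1]

    def subset_rows(self, idx) -> "CompositeDataset":
        idx = np.asarray(idx)
        return CompositeDataset(
            tuple(self.pairs[k] for k in idx), self.design[idx], self.labels[idx],
            self.feature_names, self.class_names, self.label_rule,
            None if self.responses is None else self.responses[idx])

    def subset_organisms(self, organism_ids: Iterable[str]) -> "CompositeDataset":
        keep = set(organism_ids)
        idx = [k for k, (i, j) in enumerate(self.pairs) if i in keep and j in keep]
        return self.subset_rows(idx)

    def manifest(self) -> pd.DataFrame:
        """One row per included ordered pair (the explicit design manifest)."""
        df = pd.DataFrame(self.pairs, columns=["responder", "partner"])
        df["label"] = [self.class_names[c] for c in self.labels]
        if self.responses is not None:
            df["response"] = self.responses
        return df


def assemble_dataset(
    traits: TraitMatrix,
    table: InteractionTable,
    rule: LabelRule,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> CompositeDataset:
    """Build the labelled composite dataset from traits and responses.

    Without an explicit ``pairs`` list, every ordered off-diagonal pair with
    a recorded response is included (sparse designs simply have fewer rows).
    With an explicit list, a missing response is an error.
    """
    missing_orgs = set(table.organism_ids) - set(traits.organism_ids)
    if missing_orgs:
        raise ValidationError(
            f"organisms in interaction table without trait vectors: {sorted(missing_orgs)}")
    if pairs is None:
        pairs = table.measured_pairs()
    else:
        missing = [(i, j) for i, j in pairs
                   if not np.isfinite(table.response(i, j)) or i == j]
        if missing:
            raise ValidationError(f"missing responses for requested pairs: {missing}")
    n = traits.n_features
    rows = np.empty((len(pairs), 2 * n), dtype=np.int8)
    responses = np.empty(len(pairs))
    labels = np.empty(len(pairs), dtype=np.int8)
    for k, (i, j) in enumerate(pairs):
        rows[k] = build_composite(traits.row(i), traits.row(j))
        responses[k] = table.response(i, j)
        labels[k] = rule.classify(responses[k])
    feature_names = tuple(traits.feature_names) + tuple(
        f + PARTNER_SUFFIX for f in traits.feature_names)
    return CompositeDataset(tuple(pairs), rows, labels, feature_names,
                            rule.class_names, rule.describe(), responses)


def jaccard_distance(f_i: np.ndarray, f_j: np.ndarray) -> float:
    """``1 - |intersection| / |union|`` over the positions set to 1."""
    f_i = np.asarray(f_i).astype(bool)
    f_j = np.asarray(f_j).astype(bool)
    if f_i.shape != f_j.shape:
        raise ValueError("trait vectors must have equal length")
    union = np.count_nonzero(f_i | f_j)
    if union == 0:
        raise ValueError("Jaccard distance undefined for two all-zero vectors")
    inter = np.count_nonzero(f_i & f_j)
    return 1.0 - inter / union


@dataclass(frozen=True)
class RocCurve:
    """ROC step curve plus trapezoid AUC.

    ``fpr``/``tpr`` include the (0, 0) and (1, 1) endpoints; the AUC equals
    the concordant-pair (Mann-Whitney) statistic with ties counted half.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "fpr": self.fpr, "tpr": self.tpr})


def roc_curve_from_scores(scores, labels) -> RocCurve:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and aligned")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one sample of each class")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last index of every tie group so the curve steps once per
    # distinct threshold
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.r_[0, tps[distinct]]
    fp = np.r_[0, fps[distinct]]
    # integer trapezoid sum -> single division keeps the AUC exactly equal
    # to (2*concordant + ties) / (2*P*N)
    numer = int(np.sum(np.diff(fp) * (tp[1:] + tp[:-1])))
    auc = numer / (2.0 * n_pos * n_neg)
    thresholds = np.r_[np.inf, s[distinct]]
    return RocCurve(fp / n_neg, tp / n_pos, thresholds, auc)


def score_threshold_roc(scores, labels) -> RocCurve:
    """ROC of a single scalar score swept over all thresholds.

    Higher score must mean "more positive class".  Used for the Jaccard
    distance baseline and any other one-number predictor.
    """
    return roc_curve_from_scores(scores, labels)


def jaccard_baseline_scores(traits: TraitMatrix, dataset: CompositeDataset) -> np.ndarray:
    """Jaccard distance between the two organisms of every dataset pair.

    Similar trait profiles suggest niche overlap, hence competition: small
    distance scores toward the negative class, large distance toward the
    nonnegative class, which matches the "higher = more positive" convention
    of :func:`score_threshold_roc`.
    """
    return np.array([jaccard_distance(traits.row(i), traits.row(j))
                     for i, j in dataset.pairs])
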