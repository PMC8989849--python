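"""From-scratch C4.5 decision tree with gain-ratio threshold splits.

All attributes are continuous; a split is binary (``value <= threshold`` goes
left) with candidate thresholds at midpoints between consecutive distinct
sorted values.  Attribute selection maximizes the information gain ratio

    Gain(A)      = Entropy(D) - Entropy_A(D)          (entropies in bits)
    SplitInfo(A) = -sum |D_i|/|D| * lb(|D_i|/|D|)
    GainRatio(A) = Gain(A) / SplitInfo(A)

over the two subsets induced by the threshold; candidates with zero split
information (one-sided partitions) are invalid.  In ``improved`` mode the
denominator is augmented with an attribute-redundancy penalty (see
:mod:`emoeeg.forest`): ``Gain / (SplitInfo + a * rbar)``.

Tie-breaking is deterministic: lexicographically smaller attribute name, then
smaller threshold.  Leaves take the majority class, ties resolved to the
lexicographically smaller label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SplitCandidate",
    "DecisionNode",
    "class_entropy",
    "partition_entropy",
    "split_info",
    "gain_ratio",
    "candidate_thresholds",
    "best_split",
    "build_tree",
    "predict_one",
    "C45TreeClassifier",
]

_TOL = 1e-12


# ---------------------------------------------------------------------------
# information measures (Shannon entropies, base 2)


def _entropy_from_counts(counts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Entropy in bits from class-count vectors (0 * lb 0 := 0)."""
    counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / totals, 0.0)
        logs = np.log2(np.where(p > 0, p, 1.0))
    return -(p * logs).sum(axis=axis)


def class_entropy(labels) -> float:
    """Entropy(D) = -sum p_i lb(p_i) of the class distribution, in bits."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("class_entropy of an empty label set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return float(_entropy_from_counts(counts))


def partition_entropy(values, labels, threshold: float) -> float:
    """Weighted entropy of the two subsets induced by ``value <= threshold``."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and labels must have equal length")
    mask = values <= threshold
    n = values.shape[0]
    total = 0.0
    for side in (mask, ~mask):
        k = int(side.sum())
        if k:
            total += (k / n) * class_entropy(labels[side])
    return total


def split_info(values, threshold: float) -> float:
    """SplitInfo of the binary partition, in bits (0 for one-sided splits)."""
    values = np.asarray(values, dtype=float)
    n_left = int((values <= threshold).sum())
    counts = np.array([n_left, values.shape[0] - n_left])
    return float(_entropy_from_counts(counts[counts > 0]))


@dataclass(frozen=True)
class SplitCandidate:
    """One (attribute, threshold) candidate with its split statistics."""

    attribute: str
    feature_index: int
    threshold: float
    gain: float
    split_info: float
    gain_ratio: float
    adjusted_gain_ratio: float | None = None
    valid: bool = True

    @property
    def score(self) -> float:
        """The criterion actually maximized (adjusted ratio in forest mode)."""
        return (
            self.adjusted_gain_ratio
            if self.adjusted_gain_ratio is not None
            else self.gain_ratio
        )


def gain_ratio(
    values, labels, threshold: float, attribute: str = "", feature_index: int = 0
) -> SplitCandidate:
    """Gain, split information, and gain ratio of one threshold candidate.

    Candidates with zero split information are marked invalid (a one-sided
    split is no split; Eq. ratio would divide by zero).
    """
    g = class_entropy(labels) - partition_entropy(values, labels, threshold)
    si = split_info(values, threshold)
    if si <= _TOL:
        return SplitCandidate(
            attribute, feature_index, threshold, g, si, float("nan"), valid=False
        )
    return SplitCandidate(attribute, feature_index, threshold, g, si, g / si)


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values."""
    uniq = np.unique(np.asarray(values, dtype=float))
    return (uniq[:-1] + uniq[1:]) / 2.0


# ---------------------------------------------------------------------------
# split search


def _scan_attribute(v: np.ndarray, onehot: np.ndarray):
    """Vectorized gain / split-info over every threshold of one attribute.

    Returns (thresholds, gain, split_info) arrays, or None if the attribute
    has a single distinct value.
    """
    order = np.argsort(v, kind="stable")
    vs = v[order]
    boundaries = np.nonzero(np.diff(vs) > 0)[0]
    if boundaries.size == 0:
        return None
    cum = np.cumsum(onehot[order], axis=0)
    total = cum[-1]
    n = v.shape[0]
    left = cum[boundaries]
    right = total[None, :] - left
    n_left = left.sum(axis=1)
    n_right = n - n_left
    base = _entropy_from_counts(total)
    part = (n_left / n) * _entropy_from_counts(left) + (
        n_right / n
    ) * _entropy_from_counts(right)
    gain = base - part
    si = _entropy_from_counts(np.stack([n_left, n_right], axis=1))
    thresholds = (vs[boundaries] + vs[boundaries + 1]) / 2.0
    return thresholds, gain, si


def best_split(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    allowed: Sequence[int] | None = None,
    mode: str = "plain",
    a: float = 1.0,
    redundancy: Mapping[int, float] | None = None,
    allow_zero_gain: bool = False,
) -> SplitCandidate | None:
    """Exhaustive gain-ratio maximization over all (attribute, threshold) pairs.

    ``mode='improved'`` maximizes ``gain / (split_info + a * redundancy[j])``
    instead, where ``redundancy`` maps feature index to the mean absolute
    Pearson correlation with the other candidate attributes.  Returns ``None``
    when no candidate is valid or the best achievable gain is ~0; tree growth
    passes ``allow_zero_gain=True`` to accept zero-gain splits, which is what
    lets a fully-grown tree reach purity on parity-style (XOR) patterns where
    no single threshold is informative on its own.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, n_features = X.shape
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(n_features)]
    if allowed is None:
        allowed = range(n_features)
    if mode not in ("plain", "improved"):
        raise ValueError("mode must be 'plain' or 'improved'")

    classes, codes = np.unique(y, return_inverse=True)
    onehot = np.zeros((n, classes.size))
    onehot[np.arange(n), codes] = 1.0

    best: SplitCandidate | None = None
    # lexicographic attribute order, then ascending threshold, makes the
    # argmax deterministic under ties
    for j in sorted(allowed, key=lambda j: feature_names[j]):
        scan = _scan_attribute(X[:, j], onehot)
        if scan is None:
            continue
        thresholds, gains, sis = scan
        valid = sis > _TOL
        if mode == "improved":
            rbar = float(redundancy.get(j, 0.0)) if redundancy else 0.0
            denom = sis + a * rbar
            valid &= denom > _TOL
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(valid, gains / np.where(denom > 0, denom, 1.0), -np.inf)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(valid, gains / np.where(sis > 0, sis, 1.0), -np.inf)
        if not valid.any():
            continue
        k = int(np.argmax(scores))  # first occurrence = smallest threshold on ties
        if best is None or scores[k] > best.score + _TOL:
            adj = float(scores[k]) if mode == "improved" else None
            best = SplitCandidate(
                attribute=feature_names[j],
                feature_index=int(j),
                threshold=float(thresholds[k]),
                gain=float(gains[k]),
                split_info=float(sis[k]),
                gain_ratio=float(gains[k] / sis[k]),
                adjusted_gain_ratio=adj,
            )
    if best is None or (best.gain <= _TOL and not allow_zero_gain):
        return None
    return best


# ---------------------------------------------------------------------------
# tree construction


@dataclass
class DecisionNode:
    """Internal node (attribute/threshold with two children) or class leaf."""

    counts: dict[str, int]
    n: int
    attribute: str | None = None
    feature_index: int | None = None
    threshold: float | None = None
    left: "DecisionNode | None" = None
    right: "DecisionNode | None" = None
    label: str | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        d = {"counts": dict(self.counts), "n": self.n}
        if self.is_leaf:
            d["label"] = self.label
        else:
            d.update(
                attribute=self.attribute,
                feature_index=self.feature_index,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionNode":
        if "label" in d:
            return cls(counts={k: int(v) for k, v in d["counts"].items()},
                       n=int(d["n"]), label=d["label"])
        return cls(
            counts={k: int(v) for k, v in d["counts"].items()},
            n=int(d["n"]),
            attribute=d["attribute"],
            feature_index=int(d["feature_index"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def _majority_label(counts: Counter) -> str:
    top = max(counts.values())
    return min(label for label, c in counts.items() if c == top)


def build_tree(
    X,
    y,
    feature_names: Sequence[str] | None = None,
    *,
    mode: str = "plain",
    a: float = 1.0,
    redundancy_matrix: np.ndarray | None = None,
    m_try: int | None = None,
    rng: np.random.Generator | None = None,
    max_depth: int | None = None,
    min_samples_split: int = 2,
) -> DecisionNode:
    """Recursive C4.5 construction.

    Recursion stops when a node is pure, no valid split exists, or the
    optional ``max_depth`` / ``min_samples_split`` limits hit.  With ``m_try``
    set, each node first draws that many attributes without replacement from
    ``rng`` (the random-forest attribute-subset step);
    ``redundancy_matrix[i, j]`` must then hold ``|pearson|`` between
    attributes i and j for the improved criterion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n, n_features = X.shape
    if n == 0:
        raise ValueError("cannot build a tree from an empty dataset")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(n_features)]
    if m_try is not None:
        if not 1 <= m_try <= n_features:
            raise ValueError(f"m_try must be in [1, {n_features}], got {m_try}")
        if m_try < n_features and rng is None:
            raise ValueError("m_try < n_features requires an rng")

    def grow(rows: np.ndarray, depth: int) -> DecisionNode:
        labels = y[rows]
        counts = Counter(labels.tolist())
        node = DecisionNode(counts=dict(counts), n=rows.size)
        pure = len(counts) == 1
        if (
            pure
            or rows.size < min_samples_split
            or (max_depth is not None and depth >= max_depth)
        ):
            node.label = _majority_label(counts)
            return node

        if m_try is not None and m_try < n_features:
            sel = np.sort(rng.choice(n_features, size=m_try, replace=False))
        else:
            sel = np.arange(n_features)

        redundancy = None
        if mode == "improved" and redundancy_matrix is not None and sel.size > 1:
            redundancy = {
                int(j): float(
                    np.mean([redundancy_matrix[j, k] for k in sel if k != j])
                )
                for j in sel
            }

        cand = best_split(
            X[rows], labels, feature_names, allowed=sel, mode=mode, a=a,
            redundancy=redundancy, allow_zero_gain=True,
        )
        if cand is None:
            node.label = _majority_label(counts)
            return node

        mask = X[rows, cand.feature_index] <= cand.threshold
        node.attribute = cand.attribute
        node.feature_index = cand.feature_index
        node.threshold = cand.threshold
        node.left = grow(rows[mask], depth + 1)
        node.right = grow(rows[~mask], depth + 1)
        return node

    return grow(np.arange(n), 0)


def _pessimistic_prune(node: DecisionNode) -> float:
    """Bottom-up pessimistic-error pruning (0.5 continuity correction per leaf).

    Returns the pruned subtree's pessimistic error count; collapses an
    internal node to a leaf when the leaf estimate is no worse.
    """
    if node.is_leaf:
        errors = node.n - max(node.counts.values())
        return errors + 0.5
    subtree_err = _pessimistic_prune(node.left) + _pessimistic_prune(node.right)
    leaf_err = (node.n - max(node.counts.values())) + 0.5
    if leaf_err <= subtree_err:
        node.left = node.right = None
        node.attribute = node.feature_index = node.threshold = None
        node.label = _majority_label(Counter(node.counts))
        return leaf_err
    return subtree_err


def _route(node: DecisionNode, row: np.ndarray) -> DecisionNode:
    while not node.is_leaf:
        node = node.left if row[node.feature_index] <= node.threshold else node.right
    return node


def predict_one(root: DecisionNode, values: Mapping[str, float]) -> str:
    """Classify one named feature mapping; missing attributes are an error."""
    node = root
    while not node.is_leaf:
        if node.attribute not in values:
            raise KeyError(f"feature vector lacks tested attribute {node.attribute!r}")
        node = (
            node.left if values[node.attribute] <= node.threshold else node.right
        )
    return node.label


# ---------------------------------------------------------------------------
# estimator


class C45TreeClassifier:
    """C4.5 decision tree classifier (sklearn-style estimator).

    Parameters
    ----------
    max_depth : int or None
        Optional depth limit; None grows until purity or no valid split.
    min_samples_split : int
        Nodes smaller than this become leaves.
    prune : bool
        Apply pessimistic-error pruning after construction.  Off by default:
        the improved random forest requires unpruned trees, and unpruned
        growth reproduces 100% training accuracy on consistent data.

    Attributes (after fit)
    ----------------------
    classes_ : ndarray of class labels
    tree_ : DecisionNode root
    n_features_in_, feature_names_in_
    """

    def __init__(
        self,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        prune: bool = False,
    ):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.prune = prune

    # manual get/set_params keep the estimator sklearn-clonable without a
    # runtime scikit-learn dependency
    def get_params(self, deep: bool = True) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "prune": self.prune,
        }

    def set_params(self, **params) -> "C45TreeClassifier":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _validate_X(self, X, reset: bool) -> np.ndarray:
        names = list(X.columns) if hasattr(X, "columns") else None
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        if reset:
            self.n_features_in_ = X.shape[1]
            self.feature_names_in_ = (
                names if names is not None else [f"x{j}" for j in range(X.shape[1])]
            )
        elif X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return X

    def fit(self, X, y) -> "C45TreeClassifier":
        X = self._validate_X(X, reset=True)
        y = np.asarray(y, dtype=object).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        self.classes_ = np.unique(y)
        self.tree_ = build_tree(
            X,
            y,
            self.feature_names_in_,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
        )
        if self.prune:
            _pessimistic_prune(self.tree_)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "tree_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X, reset=False)
        return np.asarray([_route(self.tree_, row).label for row in X], dtype=object)

    def predict_proba(self, X) -> np.ndarray:
        """Leaf class frequencies, columns ordered as ``classes_``."""
        self._check_fitted()
        X = self._validate_X(X, reset=False)
        proba = np.zeros((X.shape[0], self.classes_.size))
        index = {c: i for i, c in enumerate(self.classes_)}
        for i, row in enumerate(X):
            leaf = _route(self.tree_, row)
            for label, count in leaf.counts.items():
                proba[i, index[label]] = count / leaf.n
        return proba

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=object).ravel()
        return float(np.mean(self.predict(X) == y))
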