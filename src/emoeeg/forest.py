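"""Improved random forest: Pearson-adjusted splitting and weighted voting.

Two modifications of the classic bagged C4.5 forest:

1. **Redundancy-penalized attribute selection.**  Gain ratio biases splits
   toward attributes correlated with attributes already informative; at every
   node the criterion becomes

       AdjustedGainRatio(A) = Gain(A) / (SplitInfo(A) + a * rbar(A))

   where ``rbar(A)`` is the mean absolute Pearson correlation between A and
   the other attributes drawn into the node's random subset (computed on the
   tree's in-bag rows), and ``a`` weights the penalty; ``a = 0`` reduces
   exactly to plain gain ratio.

2. **Accuracy-weighted voting.**  Each unpruned tree votes with weight
   ``Ac_tree``, its accuracy on held-out rows — by default the out-of-bag
   rows, since an unpruned tree's in-bag accuracy is ~100% and would collapse
   weighting to majority voting.  Uniform weights reduce exactly to majority
   vote.  Vote ties resolve to the lexicographically smaller class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .tree import DecisionNode, build_tree, _route

__all__ = [
    "pearson",
    "attribute_redundancy",
    "improved_gain_ratio",
    "bootstrap_sample",
    "weighted_vote",
    "WeightedTree",
    "ImprovedRandomForestClassifier",
]

logger = logging.getLogger(__name__)


def pearson(x, y) -> float:
    """Product-moment correlation coefficient in [-1, 1].

    Zero-variance input is defined as r = 0 (with a logged warning) rather
    than an error, so degenerate bootstrap columns cannot poison a node.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise ValueError("pearson needs at least 2 observations")
    n = x.shape[0]
    sx = x.sum()
    sy = y.sum()
    cov = (x * y).sum() - sx * sy / n
    vx = (x * x).sum() - sx * sx / n
    vy = (y * y).sum() - sy * sy / n
    if vx <= 0 or vy <= 0:
        logger.warning("pearson on zero-variance input; defining r = 0")
        return 0.0
    r = cov / math.sqrt(vx * vy)
    return float(min(1.0, max(-1.0, r)))


def attribute_redundancy(X, candidate: int, reference: list[int]) -> float:
    """Mean absolute Pearson correlation of one attribute against a reference
    set (the candidate itself excluded); empty reference set gives 0."""
    X = np.asarray(X, dtype=float)
    refs = [j for j in reference if j != candidate]
    if not refs:
        return 0.0
    return float(np.mean([abs(pearson(X[:, candidate], X[:, j])) for j in refs]))


def improved_gain_ratio(gain: float, split_info: float, a: float, rbar: float) -> float:
    """``Gain / (SplitInfo + a * rbar)``; non-positive denominators are invalid."""
    denom = split_info + a * rbar
    if denom <= 0:
        raise ValueError(
            f"invalid candidate: split_info + a*rbar = {denom} must be positive"
        )
    return gain / denom


def bootstrap_sample(
    n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n row indices with replacement; returns (in_bag, out_of_bag).

    The out-of-bag set is the rows never drawn (expected fraction -> 1/e).
    """
    if n < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    in_bag = np.sort(rng.integers(0, n, size=n))
    mask = np.zeros(n, dtype=bool)
    mask[in_bag] = True
    return in_bag, np.nonzero(~mask)[0]


def weighted_vote(predictions, weights, *, return_shares: bool = False):
    """Argmax of summed per-class weights; ties -> lexicographically smaller.

    With equal weights this is exactly the majority vote.  ``return_shares``
    additionally returns the normalized per-class weight totals.
    """
    predictions = list(predictions)
    weights = np.asarray(weights, dtype=float)
    if len(predictions) != weights.shape[0]:
        raise ValueError("predictions and weights must have equal length")
    if len(predictions) == 0:
        raise ValueError("cannot vote with zero trees")
    totals: dict[str, float] = {}
    for label, w in zip(predictions, weights):
        totals[label] = totals.get(label, 0.0) + float(w)
    top = max(totals.values())
    winner = min(label for label, t in totals.items() if t >= top - 1e-12)
    if not return_shares:
        return winner
    grand = sum(totals.values())
    shares = {label: t / grand for label, t in totals.items()} if grand > 0 else totals
    return winner, shares


def _abs_correlation_matrix(X: np.ndarray) -> np.ndarray:
    """|r| between all attribute pairs; zero-variance columns give 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    corr = np.nan_to_num(corr, nan=0.0)
    return np.abs(corr)


@dataclass
class WeightedTree:
    """One forest member: the unpruned tree, its vote weight, and its bag."""

    tree: DecisionNode
    weight: float
    in_bag: np.ndarray
    out_of_bag: np.ndarray


class ImprovedRandomForestClassifier:
    """Random forest of unpruned C4.5 trees with the two improvements above.

    Parameters
    ----------
    n_estimators : int
        Number of trees T.
    max_features : "sqrt", int, or None
        Attributes drawn per node (m); "sqrt" -> ceil(sqrt(M)), None -> M.
    redundancy_weight : float
        The penalty weight ``a``; 0 recovers plain gain-ratio splitting.
    split_criterion : {"improved", "plain"}
        Node criterion; "plain" ignores the redundancy term entirely (used
        to verify the ``a = 0`` reduction).
    weighting : {"accuracy_weighted", "majority"}
        Vote rule; "majority" gives every tree weight 1.
    weight_on : {"oob", "in_bag"}
        Rows used to measure Ac_tree.  Out-of-bag is the default unbiased
        surrogate; if a tree's OOB set is empty its in-bag accuracy is used
        with a logged warning.
    bootstrap : bool
        False replaces the bootstrap with the identity sample (every tree
        sees all rows; OOB empty) — useful to reduce the forest to a bag of
        identically-trained trees in tests.
    random_state : int or None
        Seed for the per-tree RNG streams (deterministic spawn).
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_features: str | int | None = "sqrt",
        redundancy_weight: float = 1.0,
        split_criterion: str = "improved",
        weighting: str = "accuracy_weighted",
        weight_on: str = "oob",
        max_depth: int | None = None,
        min_samples_split: int = 2,
        bootstrap: bool = True,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.redundancy_weight = redundancy_weight
        self.split_criterion = split_criterion
        self.weighting = weighting
        self.weight_on = weight_on
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.bootstrap = bootstrap
        self.random_state = random_state

    _param_names = (
        "n_estimators",
        "max_features",
        "redundancy_weight",
        "split_criterion",
        "weighting",
        "weight_on",
        "max_depth",
        "min_samples_split",
        "bootstrap",
        "random_state",
    )

    def get_params(self, deep: bool = True) -> dict:
        return {name: getattr(self, name) for name in self._param_names}

    def set_params(self, **params) -> "ImprovedRandomForestClassifier":
        for key, value in params.items():
            if key not in self._param_names:
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def _resolve_m_try(self, n_features: int) -> int:
        if self.max_features is None:
            return n_features
        if self.max_features == "sqrt":
            return int(math.ceil(math.sqrt(n_features)))
        m = int(self.max_features)
        if not 1 <= m <= n_features:
            raise ValueError(
                f"max_features={m} outside [1, {n_features}]"
            )
        return m

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

    def fit(self, X, y) -> "ImprovedRandomForestClassifier":
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if self.split_criterion not in ("improved", "plain"):
            raise ValueError("split_criterion must be 'improved' or 'plain'")
        if self.weighting not in ("accuracy_weighted", "majority"):
            raise ValueError("weighting must be 'accuracy_weighted' or 'majority'")
        if self.weight_on not in ("oob", "in_bag"):
            raise ValueError("weight_on must be 'oob' or 'in_bag'")
        X = self._validate_X(X, reset=True)
        y = np.asarray(y, dtype=object).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        n, n_features = X.shape
        self.classes_ = np.unique(y)
        m_try = self._resolve_m_try(n_features)

        seed_seq = np.random.SeedSequence(self.random_state)
        self.estimators_: list[WeightedTree] = []
        for child in seed_seq.spawn(self.n_estimators):
            rng = np.random.default_rng(child)
            if self.bootstrap:
                in_bag, oob = bootstrap_sample(n, rng)
            else:
                in_bag, oob = np.arange(n), np.array([], dtype=int)
            Xb, yb = X[in_bag], y[in_bag]

            redundancy_matrix = None
            if self.split_criterion == "improved" and n_features > 1:
                redundancy_matrix = _abs_correlation_matrix(Xb)

            root = build_tree(
                Xb,
                yb,
                self.feature_names_in_,
                mode=self.split_criterion,
                a=self.redundancy_weight,
                redundancy_matrix=redundancy_matrix,
                m_try=m_try,
                rng=rng,
                max_depth=self.max_depth,
                min_samples_split=self.min_samples_split,
            )
            weight = self._tree_weight(root, X, y, in_bag, oob)
            self.estimators_.append(WeightedTree(root, weight, in_bag, oob))
        return self

    def _tree_weight(self, root, X, y, in_bag, oob) -> float:
        if self.weighting == "majority":
            return 1.0
        rows = oob if (self.weight_on == "oob" and oob.size > 0) else in_bag
        if self.weight_on == "oob" and oob.size == 0:
            logger.warning("empty out-of-bag set; falling back to in-bag accuracy")
        correct = sum(
            1 for i in rows if _route(root, X[i]).label == y[i]
        )
        return correct / rows.size

    def _check_fitted(self) -> None:
        if not hasattr(self, "estimators_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def _tree_predictions(self, X: np.ndarray) -> list[list[str]]:
        return [
            [_route(member.tree, row).label for member in self.estimators_]
            for row in X
        ]

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._validate_X(X, reset=False)
        weights = [member.weight for member in self.estimators_]
        return np.asarray(
            [weighted_vote(preds, weights) for preds in self._tree_predictions(X)],
            dtype=object,
        )

    def predict_proba(self, X) -> np.ndarray:
        """Normalized per-class vote-weight shares, columns as ``classes_``."""
        self._check_fitted()
        X = self._validate_X(X, reset=False)
        weights = [member.weight for member in self.estimators_]
        index = {c: i for i, c in enumerate(self.classes_)}
        proba = np.zeros((X.shape[0], self.classes_.size))
        for i, preds in enumerate(self._tree_predictions(X)):
            _, shares = weighted_vote(preds, weights, return_shares=True)
            for label, share in shares.items():
                proba[i, index[label]] = share
        return proba

    def score(self, X, y) -> float:
        y = np.asarray(y, dtype=object).ravel()
        return float(np.mean(self.predict(X) == y))
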