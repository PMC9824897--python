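"""Three base classifiers and their weighted fusion.

* AdaBoost over depth-1 decision stumps, built directly from the weighted
  classification error phi_c = sum_s p_s 1[u(v_s) != t_s] and learner
  weight tau_c = 0.5 ln((1-phi_c)/phi_c), with the multiplicative
  exponential sample-reweighting that is consistent with that weight.
  Labels are handled internally in {-1, +1}; the strong classifier is
  sign(sum_c tau_c u_c(v)).
* A greedy CART-style decision tree splitting on the largest Gini
  impurity decrease, with deterministic tie-breaking (lowest feature
  index, then lowest threshold).
* A random forest (bootstrap size Q = n, h = floor(sqrt(D)) features
  redrawn per node, unpruned trees, majority vote), delegated to
  scikit-learn's RandomForestClassifier behind this module's surface.

The ensemble output is the convex combination
``E_c = tau*E_AB + rho*E_RF + eps*E_DT`` of the three base models'
class-1 scores in [0, 1], with (tau, rho, eps) on the probability simplex;
the predicted label is 1 iff the fused score is at least 0.5.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, TrainingError

ARCHIVE_VERSION = "hybridseek-ensemble-1"

_PHI_CLAMP = 1e-10
_SIMPLEX_TOL = 1e-9


# --------------------------------------------------------------------------
# AdaBoost over decision stumps


@dataclass
class WeakLearner:
    """A decision stump: predict ``polarity`` if x[feature] > threshold."""

    feature: int
    threshold: float
    polarity: int  # +1: predict +1 above the threshold; -1: the reverse

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        above = X[:, self.feature] > self.threshold
        return np.where(above, self.polarity, -self.polarity).astype(int)


def weighted_error(predictions, labels, sample_weights) -> float:
    """Weighted misclassification rate of one learner (Eq.-style phi)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    w = np.asarray(sample_weights, dtype=float)
    if np.any(w < 0):
        raise ParameterError("sample weights must be non-negative")
    if abs(w.sum() - 1.0) > _SIMPLEX_TOL:
        raise ParameterError(f"sample weights must sum to 1, got {w.sum()!r}")
    return float(np.sum(w * (predictions != labels)))


def learner_weight(phi: float) -> float:
    """Vote weight tau = 0.5 ln((1-phi)/phi), with phi clamped away from
    0 and 1 so the weight stays finite."""
    phi = min(max(float(phi), _PHI_CLAMP), 1.0 - _PHI_CLAMP)
    return 0.5 * math.log((1.0 - phi) / phi)


def _fit_stump(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[WeakLearner, float]:
    """Exhaustively fit the stump minimizing weighted error.

    Deterministic: candidates are scanned feature-ascending and
    threshold-ascending, replacing the incumbent only on strict
    improvement.
    """
    n, d = X.shape
    best_err = np.inf
    best = None
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        ys = y[order]
        # err_pos(t) for "predict +1 when x > t": positives at or below t
        # plus negatives above t, evaluated at every prefix boundary.
        wpos = np.where(ys == 1, ws, 0.0)
        wneg = ws - wpos
        cum_pos = np.concatenate(([0.0], np.cumsum(wpos)))
        cum_neg = np.concatenate(([0.0], np.cumsum(wneg)))
        total_neg = cum_neg[-1]
        err_pos = cum_pos + (total_neg - cum_neg)
        # candidate thresholds: below the minimum, then midpoints at value
        # changes; boundaries inside runs of equal values are skipped
        boundaries = np.concatenate(([0], np.nonzero(np.diff(xs))[0] + 1))
        thresholds = np.empty(len(boundaries))
        thresholds[0] = xs[0] - 1.0
        thresholds[1:] = 0.5 * (xs[boundaries[1:] - 1] + xs[boundaries[1:]])
        # scan order: threshold-ascending, polarity +1 before -1 per
        # threshold; argmin takes the first minimum, preserving tie-breaks
        errs = np.empty(2 * len(boundaries))
        errs[0::2] = err_pos[boundaries]
        errs[1::2] = 1.0 - err_pos[boundaries]
        k = int(np.argmin(errs))
        err = float(errs[k])
        if err < best_err - 1e-15:
            best_err = err
            best = WeakLearner(
                j, float(thresholds[k // 2]), 1 if k % 2 == 0 else -1
            )
    assert best is not None
    return best, float(best_err)


@dataclass
class AdaBoostModel:
    learners: list[WeakLearner] = field(default_factory=list)
    weights: list[float] = field(default_factory=list)  # tau_c

    @property
    def rounds(self) -> int:
        return len(self.learners)

    def margin(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        total = np.zeros(len(X))
        for learner, tau in zip(self.learners, self.weights):
            total += tau * learner.predict(X)
        return total

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1}; the zero margin maps to +1."""
        return np.where(self.margin(X) >= 0, 1, -1)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Normalized margin mapped to [0, 1] (0.5 = undecided)."""
        norm = float(np.sum(np.abs(self.weights)))
        if norm == 0.0:
            return np.full(len(np.atleast_2d(X)), 0.5)
        return 0.5 * (self.margin(X) / norm + 1.0)


def adaboost_train(X, y, rounds: int = 30) -> AdaBoostModel:
    """Boost decision stumps for up to ``rounds`` rounds.

    ``y`` may be {0, 1} or {-1, +1}.  Training halts early when a round's
    best stump is no better than chance (phi >= 0.5) or when training is
    already perfect.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    if len(X) < 2:
        raise TrainingError("adaboost_train needs at least 2 samples")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("adaboost_train needs both classes present")
    t = np.where(y == classes.max(), 1, -1)

    n = len(X)
    p = np.full(n, 1.0 / n)
    model = AdaBoostModel()
    for _ in range(rounds):
        stump, phi = _fit_stump(X, t, p)
        if phi >= 0.5 and model.rounds > 0:
            break
        tau = learner_weight(phi)
        model.learners.append(stump)
        model.weights.append(tau)
        if phi >= 0.5:
            break
        pred = stump.predict(X)
        p = p * np.exp(-tau * t * pred)
        p = p / p.sum()
        if phi <= _PHI_CLAMP:
            break
    return model


# --------------------------------------------------------------------------
# Decision tree (greedy Gini)


def gini_impurity(class_proportions) -> float:
    """Gini impurity 1 - sum(p^2) of a class distribution."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > _SIMPLEX_TOL:
        raise ParameterError("class proportions must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


@dataclass
class TreeNode:
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    distribution: np.ndarray | None = None  # (p_class0, p_class1) at leaves

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class TreeModel:
    root: TreeNode
    max_depth: int | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        """Class-1 proportion of the leaf each sample falls into."""
        X = np.atleast_2d(X)
        out = np.empty(len(X))
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[node.feature] <= node.threshold else node.right
            out[i] = node.distribution[1]
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0.5).astype(int)


def _gini_counts(n1: float, n: float) -> float:
    if n == 0:
        return 0.0
    p1 = n1 / n
    return 1.0 - p1 * p1 - (1.0 - p1) ** 2


def best_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int = 1
) -> tuple[int, float, float] | None:
    """Exhaustive best first split by Gini decrease.

    Returns (feature, threshold, impurity_decrease) or None when no valid
    split exists.  Ties break toward the lowest feature index, then the
    lowest threshold.
    """
    n, d = X.shape
    total1 = float(np.sum(y))
    parent = _gini_counts(total1, n)
    best = None
    best_gain = 0.0
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        cum1 = np.cumsum(ys)
        change = np.nonzero(np.diff(xs))[0]  # split after index i -> left size i+1
        if len(change) == 0:
            continue
        nl = change + 1.0
        nr = n - nl
        valid = (nl >= min_leaf) & (nr >= min_leaf)
        if not valid.any():
            continue
        change = change[valid]
        nl = nl[valid]
        nr = nr[valid]
        l1 = cum1[change].astype(float)
        r1 = total1 - l1
        gl = 1.0 - (l1 / nl) ** 2 - (1.0 - l1 / nl) ** 2
        gr = 1.0 - (r1 / nr) ** 2 - (1.0 - r1 / nr) ** 2
        gains = parent - (nl / n) * gl - (nr / n) * gr
        k = int(np.argmax(gains))  # first maximum = lowest threshold
        if gains[k] > best_gain + 1e-15:
            best_gain = float(gains[k])
            i = change[k]
            best = (j, float(0.5 * (xs[i] + xs[i + 1])), best_gain)
    return best


def _grow(X, y, depth, max_depth, min_leaf) -> TreeNode:
    n = len(y)
    n1 = float(np.sum(y))
    dist = np.array([(n - n1) / n, n1 / n])
    if (
        n1 in (0.0, float(n))
        or (max_depth is not None and depth >= max_depth)
        or n < 2 * min_leaf
    ):
        return TreeNode(distribution=dist)
    split = best_split(X, y, min_leaf)
    if split is None:
        return TreeNode(distribution=dist)
    j, t, _ = split
    mask = X[:, j] <= t
    return TreeNode(
        feature=j,
        threshold=t,
        left=_grow(X[mask], y[mask], depth + 1, max_depth, min_leaf),
        right=_grow(X[~mask], y[~mask], depth + 1, max_depth, min_leaf),
    )


def dt_train(X, y, max_depth: int | None = None, min_leaf: int = 1) -> TreeModel:
    """Greedy recursive binary splitting on Gini impurity decrease.

    Deterministic given the data; duplicated rows with conflicting labels
    end in a leaf holding the proportional class distribution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    if len(X) < 2:
        raise TrainingError("dt_train needs at least 2 samples")
    if min_leaf < 1:
        raise ParameterError("min_leaf must be >= 1")
    return TreeModel(root=_grow(X, y, 0, max_depth, min_leaf), max_depth=max_depth)


# --------------------------------------------------------------------------
# Random forest (delegated internals)


@dataclass
class ForestModel:
    """Unpruned bootstrap forest with per-node feature subsampling."""

    estimator: RandomForestClassifier
    n_trees: int
    n_sub_features: int
    bootstrap_size: int

    def score(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting class 1."""
        proba = self.estimator.predict_proba(np.atleast_2d(X))
        idx = list(self.estimator.classes_).index(1)
        return proba[:, idx]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.score(X) >= 0.5).astype(int)


def rf_train(
    X,
    y,
    n_trees: int = 50,
    n_sub_features: int | None = None,
    seed: int | None = None,
    bootstrap: bool = True,
) -> ForestModel:
    """Train a forest of ``n_trees`` unpruned trees.

    Each tree sees a bootstrap sample of size Q = n and redraws
    ``n_sub_features`` (default floor(sqrt(D)), required < D) candidate
    features at every node.  A fixed seed gives an identical forest.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int)
    n, d = X.shape
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    if n_sub_features is None:
        n_sub_features = max(1, int(math.floor(math.sqrt(d))))
    if not n_sub_features < d:
        raise ParameterError(
            f"n_sub_features ({n_sub_features}) must be < n_features ({d})"
        )
    if len(np.unique(y)) < 2:
        raise TrainingError("rf_train needs both classes present")
    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=n_sub_features,
        bootstrap=bootstrap,
        random_state=seed,
        criterion="gini",
    )
    est.fit(X, y)
    return ForestModel(
        estimator=est,
        n_trees=n_trees,
        n_sub_features=n_sub_features,
        bootstrap_size=n if bootstrap else 0,
    )


# --------------------------------------------------------------------------
# Weighted fusion


def _check_simplex(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,):
        raise ParameterError("fusion weights must be a length-3 vector")
    if np.any(w < -_SIMPLEX_TOL) or np.any(w > 1 + _SIMPLEX_TOL):
        raise ParameterError(f"fusion weights must lie in [0, 1]: {w}")
    if abs(w.sum() - 1.0) > _SIMPLEX_TOL:
        raise ParameterError(f"fusion weights must sum to 1, got {w.sum()!r}")
    return w


@dataclass
class EnsembleModel:
    """Trained AdaBoost + random forest + decision tree with fusion weights
    (tau, rho, eps) on the probability simplex."""

    adaboost: AdaBoostModel
    forest: ForestModel
    tree: TreeModel
    fusion_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self):
        _check_simplex(self.fusion_weights)

    def base_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, 3) array of class-1 scores: AdaBoost, forest, tree."""
        X = np.atleast_2d(X)
        return np.column_stack(
            [self.adaboost.score(X), self.forest.score(X), self.tree.score(X)]
        )

    def save(self, path) -> None:
        payload = {"version": ARCHIVE_VERSION, "model": self}
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @staticmethod
    def load(path) -> "EnsembleModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if not isinstance(payload, dict) or payload.get("version") != ARCHIVE_VERSION:
            raise ParameterError(f"{path}: not a recognized model archive")
        model = payload["model"]
        _check_simplex(model.fusion_weights)
        if model.adaboost.rounds < 1:
            raise ParameterError("archive holds an empty AdaBoost model")
        return model


def fuse_predict(model: EnsembleModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Fused class-1 scores and hard labels.

    The fused score is the convex combination of the base scores with the
    model's fusion weights; the label is 1 iff the score is >= 0.5.
    """
    w = _check_simplex(model.fusion_weights)
    scores = model.base_scores(X)
    fused = scores @ w
    return fused, (fused >= 0.5).astype(int)
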