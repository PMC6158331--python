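"""Per-epoch scoring detectors.

Three detectors, each exposing a continuous per-epoch score:

* line-length thresholding on the z-scored line-length feature (stats per
  1-h block),
* a from-scratch Random Forest (bagging, Gini splits, mtry = ceil(sqrt(N))
  random candidate features per node, out-of-bag error),
* a soft-margin RBF-SVM with z-score feature normalization and a
  (C, gamma) grid search under stratified k-fold CV.  The quadratic
  program itself is delegated to scikit-learn's SVC; the contract here is
  the resulting decision function, not the solver.

Multichannel fusion: logical OR of binary detections, or per-epoch max of
continuous scores (its thresholded form is identical to OR).
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import DegenerateDataError, InvalidInputError
from .features import LINE_LENGTH_INDEX

# ---------------------------------------------------------------------------
# line length detector
# ---------------------------------------------------------------------------


@dataclass
class LineLengthModel:
    """Per-block z-scoring stats for the line-length feature."""

    mean: float
    std: float
    threshold: float = 3.0  # z-score units

    def __post_init__(self):
        if not self.std > 0:
            raise DegenerateDataError("line-length std must be > 0 for z-scoring")


def ll_block_stats(line_lengths: np.ndarray, mask: np.ndarray | None = None) -> LineLengthModel:
    """Mean/std of the line length over one block (masked epochs excluded)."""
    ll = np.asarray(line_lengths, dtype=float)
    if mask is not None:
        ll = ll[~np.asarray(mask, dtype=bool)]
    if ll.size < 2:
        raise InvalidInputError("need >= 2 epochs for block stats")
    std = float(ll.std())
    return LineLengthModel(mean=float(ll.mean()), std=std)


def ll_score(line_lengths: np.ndarray, model: LineLengthModel) -> np.ndarray:
    """Per-epoch z-scores; detection at ``z > model.threshold``."""
    return (np.asarray(line_lengths, dtype=float) - model.mean) / model.std


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------


def gini_impurity(counts: Sequence[float]) -> float:
    """G = 1 - sum_c p_c^2 for class counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise InvalidInputError("counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise InvalidInputError("empty node")
    p = counts / n
    return float(1.0 - (p**2).sum())


def gini_impurity_decrease(
    parent_counts: Sequence[float],
    left_counts: Sequence[float],
    right_counts: Sequence[float],
) -> float:
    """Impurity decrease of a binary split; left + right must equal parent."""
    parent = np.asarray(parent_counts, dtype=float)
    left = np.asarray(left_counts, dtype=float)
    right = np.asarray(right_counts, dtype=float)
    if not np.allclose(left + right, parent):
        raise InvalidInputError("left + right counts must equal parent counts")
    n = parent.sum()
    n_l, n_r = left.sum(), right.sum()
    g = gini_impurity(parent)
    g_l = gini_impurity(left) if n_l > 0 else 0.0
    g_r = gini_impurity(right) if n_r > 0 else 0.0
    return float(g - (n_l / n) * g_l - (n_r / n) * g_r)


@dataclass
class Tree:
    """Flat-array binary decision tree.

    Node ``i`` is a leaf iff ``leaf_label[i] >= 0``; leaves self-loop in
    ``left``/``right`` so vectorized traversal can run a fixed number of
    steps.  Internal rule: go left iff ``x[feature[i]] <= threshold[i]``.
    """

    feature: np.ndarray  # int16, -1 at leaves
    threshold: np.ndarray  # float64, 0 at leaves
    left: np.ndarray  # int32
    right: np.ndarray  # int32
    leaf_label: np.ndarray  # int8, -1 internal, else 0/1

    @property
    def n_nodes(self) -> int:
        return self.feature.size

    def predict(self, x2: np.ndarray) -> np.ndarray:
        """Labels for rows of ``x2`` (n, n_features)."""
        cur = np.zeros(x2.shape[0], dtype=np.int32)
        while True:
            internal = self.leaf_label[cur] < 0
            if not internal.any():
                break
            idx = np.where(internal)[0]
            f = self.feature[cur[idx]]
            go_left = x2[idx, f] <= self.threshold[cur[idx]]
            cur[idx] = np.where(go_left, self.left[cur[idx]], self.right[cur[idx]])
        return self.leaf_label[cur].astype(np.int8)


@dataclass
class ForestModel:
    trees: list[Tree]
    mtry: int
    n_features: int
    oob_error: float
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_nodes(self) -> int:
        return sum(t.n_nodes for t in self.trees)


def _best_split(x: np.ndarray, y: np.ndarray, feats: np.ndarray):
    """Exhaustive Gini-optimal (feature, threshold) over candidate features.

    Tie-breaking: lowest feature index, then lowest threshold (features are
    scanned in ascending order and thresholds ascend within a feature, so
    keeping the first strict maximum realizes both rules).
    """
    n = y.size
    total_pos = int(y.sum())
    parent_gini = 1.0 - ((total_pos / n) ** 2 + ((n - total_pos) / n) ** 2)
    best = None  # (gain, feature, threshold)
    for f in np.sort(feats):
        v = x[:, f]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        ys = y[order]
        cut = np.where(vs[:-1] < vs[1:])[0]  # split after position i
        if cut.size == 0:
            continue
        pos_cum = np.cumsum(ys)
        n_l = cut + 1.0
        n_r = n - n_l
        pos_l = pos_cum[cut]
        pos_r = total_pos - pos_l
        g_l = 1.0 - ((pos_l / n_l) ** 2 + ((n_l - pos_l) / n_l) ** 2)
        g_r = 1.0 - ((pos_r / n_r) ** 2 + ((n_r - pos_r) / n_r) ** 2)
        gain = parent_gini - (n_l / n) * g_l - (n_r / n) * g_r
        k = int(np.argmax(gain))
        if best is None or gain[k] > best[0] + 1e-15:
            best = (float(gain[k]), int(f), 0.5 * (vs[cut[k]] + vs[cut[k] + 1]))
    return best


def _grow_tree(
    x: np.ndarray,
    y: np.ndarray,
    mtry: int,
    min_samples_split: int,
    rng: np.random.Generator,
) -> Tree:
    n_features = x.shape[1]
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    label: list[int] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(0)
        right.append(0)
        label.append(-1)
        return len(feature) - 1

    root = new_node()
    stack = [(root, np.arange(y.size))]
    while stack:
        node, idx = stack.pop()
        ys = y[idx]
        n_pos = int(ys.sum())
        if n_pos == 0 or n_pos == ys.size or ys.size < min_samples_split:
            label[node] = int(n_pos * 2 > ys.size)
            left[node] = right[node] = node
            continue
        feats = rng.choice(n_features, size=min(mtry, n_features), replace=False)
        split = _best_split(x[idx], ys, feats)
        if split is None or split[0] <= 0.0:
            label[node] = int(n_pos * 2 > ys.size)
            left[node] = right[node] = node
            continue
        _, f, thr = split
        go_left = x[idx, f] <= thr
        feature[node] = f
        threshold[node] = thr
        l_id, r_id = new_node(), new_node()
        left[node], right[node] = l_id, r_id
        # push right first so left subtree is laid out depth-first
        stack.append((r_id, idx[~go_left]))
        stack.append((l_id, idx[go_left]))
    return Tree(
        feature=np.asarray(feature, dtype=np.int16),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.int32),
        right=np.asarray(right, dtype=np.int32),
        leaf_label=np.asarray(label, dtype=np.int8),
    )


def default_mtry(n_features: int) -> int:
    """ceil(sqrt(N)) candidate features per node (4 for the 10-feature set)."""
    return math.ceil(math.sqrt(n_features))


def rf_train(
    x: np.ndarray,
    y: np.ndarray,
    n_trees: int = 100,
    mtry: int | None = None,
    min_samples_split: int = 5,
    seed: int = 0,
    balanced_bootstrap: bool = False,
) -> ForestModel:
    """Grow a bagged forest of Gini-split trees.

    Each tree sees a bootstrap sample of the training set (sampling with
    replacement, same size; ~63.2% unique rows, i.e. about two thirds);
    its out-of-bag rows contribute to the OOB error estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(np.int8)
    if x.ndim != 2 or x.shape[0] != y.size:
        raise InvalidInputError("x must be (n_samples, n_features) matching y")
    if np.unique(y).size < 2:
        raise InvalidInputError("training data must contain both classes")
    n, n_features = x.shape
    if mtry is None:
        mtry = default_mtry(n_features)
    rng = np.random.default_rng(seed)
    trees: list[Tree] = []
    oob_votes = np.zeros(n)
    oob_counts = np.zeros(n)
    pos_idx = np.where(y == 1)[0]
    neg_idx = np.where(y == 0)[0]
    for _ in range(n_trees):
        if balanced_bootstrap:
            m = min(pos_idx.size, neg_idx.size)
            boot = np.concatenate(
                [rng.choice(pos_idx, size=m, replace=True), rng.choice(neg_idx, size=m, replace=True)]
            )
        else:
            boot = rng.integers(0, n, size=n)
        xb, yb = x[boot], y[boot]
        if np.unique(yb).size < 2:  # resample a degenerate bootstrap
            boot = np.concatenate([rng.choice(pos_idx, 1), rng.choice(neg_idx, 1), boot[2:]])
            xb, yb = x[boot], y[boot]
        tree = _grow_tree(xb, yb, mtry, min_samples_split, rng)
        trees.append(tree)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        if oob.size:
            oob_votes[oob] += tree.predict(x[oob])
            oob_counts[oob] += 1
    seen = oob_counts > 0
    if seen.any():
        oob_pred = (oob_votes[seen] / oob_counts[seen]) > 0.5
        oob_error = float((oob_pred != (y[seen] == 1)).mean())
    else:  # pragma: no cover
        oob_error = float("nan")
    return ForestModel(trees=trees, mtry=mtry, n_features=n_features, oob_error=oob_error, seed=seed)


def rf_score(forest: ForestModel, x: np.ndarray) -> np.ndarray:
    """Fraction of trees voting seizure, per row of ``x``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    votes = np.zeros(x.shape[0])
    for tree in forest.trees:
        votes += tree.predict(x)
    return votes / forest.n_trees


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------

#: C = 2^-5 .. 2^15, gamma = 2^-15 .. 2^3, stepping by powers of four
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0**e for e in range(-15, 4, 2))


@dataclass
class SvmModel:
    svc: SVC
    c: float
    gamma: float
    feat_mean: np.ndarray
    feat_std: np.ndarray
    cv_accuracy: float
    threshold: float = 0.0

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.feat_mean) / self.feat_std


def rbf_kernel_value(x: np.ndarray, y: np.ndarray, gamma: float) -> float:
    """K(x, y) = exp(-gamma * |x - y|^2)."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.exp(-gamma * (d**2).sum()))


def svm_train(
    x: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    folds: int = 5,
    seed: int = 0,
) -> SvmModel:
    """Grid-searched soft-margin RBF classifier.

    Features are z-scored with training-set stats; each (C, gamma) pair is
    scored by stratified k-fold CV accuracy on the training set and the
    model is refit on all data at the best pair.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size < 2:
        raise InvalidInputError("training data must contain both classes")
    if len(c_grid) == 0 or len(gamma_grid) == 0:
        raise InvalidInputError("parameter grids must be non-empty")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    xn = (x - mean) / std
    n_per_class = np.bincount(y).min()
    folds_eff = max(2, min(folds, int(n_per_class)))
    best = None  # (acc, -C, -gamma, C, gamma)
    if len(c_grid) * len(gamma_grid) > 1:
        skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
        splits = list(skf.split(xn, y))
        for c in c_grid:
            for g in gamma_grid:
                accs = []
                for tr, te in splits:
                    svc = SVC(C=c, gamma=g, kernel="rbf")
                    svc.fit(xn[tr], y[tr])
                    accs.append(float((svc.predict(xn[te]) == y[te]).mean()))
                acc = float(np.mean(accs))
                cand = (acc, -c, -g, c, g)
                if best is None or cand[:3] > best[:3]:
                    best = cand
        cv_acc, _, _, c_best, g_best = best
    else:
        c_best, g_best, cv_acc = c_grid[0], gamma_grid[0], float("nan")
    svc = SVC(C=c_best, gamma=g_best, kernel="rbf")
    svc.fit(xn, y)
    return SvmModel(
        svc=svc, c=c_best, gamma=g_best, feat_mean=mean, feat_std=std, cv_accuracy=cv_acc
    )


def svm_score(model: SvmModel, x: np.ndarray) -> np.ndarray:
    """Signed decision values; detection at ``value > model.threshold``."""
    return model.svc.decision_function(model.normalize(np.atleast_2d(x)))


def svm_decision_expansion(model: SvmModel, x: np.ndarray) -> float:
    """sum_i alpha_i y_i K(sv_i, x) + b, computed from stored vectors.

    Redundant with :func:`svm_score`; kept as the documented decision-
    function contract (and exercised against it in the tests).
    """
    xn = model.normalize(np.atleast_2d(x))[0]
    sv = model.svc.support_vectors_
    dual = model.svc.dual_coef_[0]
    k = np.exp(-model.gamma * ((sv - xn) ** 2).sum(axis=1))
    return float((dual * k).sum() + model.svc.intercept_[0])


# ---------------------------------------------------------------------------
# multichannel fusion
# ---------------------------------------------------------------------------


def fuse_channels(per_channel: np.ndarray, mode: str = "max") -> np.ndarray:
    """Fuse (n_channels, n_epochs) outputs across 1-4 channels.

    ``mode='or'`` expects booleans and ORs them; ``mode='max'`` takes the
    per-epoch maximum score (thresholding the max reproduces the OR of
    per-channel threshold detections).
    """
    arr = np.atleast_2d(np.asarray(per_channel))
    if arr.ndim != 2:
        raise InvalidInputError("per_channel must be (n_channels, n_epochs)")
    if mode == "or":
        return arr.astype(bool).any(axis=0)
    if mode == "max":
        return arr.max(axis=0)
    raise InvalidInputError(f"unknown fusion mode {mode!r}")


# ---------------------------------------------------------------------------
# uniform detector API used by the evaluation driver
# ---------------------------------------------------------------------------


class LineLengthDetector:
    """Training-free detector; scores a block from its own stats."""

    name = "ll"
    requires_block_stats = True
    default_threshold = 3.0

    def fit(self, x: np.ndarray, y: np.ndarray) -> "LineLengthDetector":
        return self  # z-scoring stats are per evaluated block, not trained

    def score_block(self, x: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        ll = x[:, LINE_LENGTH_INDEX]
        return ll_score(ll, ll_block_stats(ll, mask))


class RandomForestDetector:
    name = "rf"
    requires_block_stats = False
    default_threshold = 0.5

    def __init__(self, n_trees: int = 100, mtry: int | None = None, seed: int = 0, **kw):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.kw = kw
        self.model: ForestModel | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "RandomForestDetector":
        self.model = rf_train(x, y, n_trees=self.n_trees, mtry=self.mtry, seed=self.seed, **self.kw)
        return self

    def score(self, x: np.ndarray) -> np.ndarray:
        assert self.model is not None, "fit before score"
        return rf_score(self.model, x)


class SvmDetector:
    name = "svm"
    requires_block_stats = False
    default_threshold = 0.0

    def __init__(
        self,
        c_grid: Sequence[float] = DEFAULT_C_GRID,
        gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
        folds: int = 5,
        seed: int = 0,
        max_train: int | None = None,
    ):
        self.c_grid = c_grid
        self.gamma_grid = gamma_grid
        self.folds = folds
        self.seed = seed
        self.max_train = max_train
        self.model: SvmModel | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "SvmDetector":
        if self.max_train is not None and x.shape[0] > self.max_train:
            # stratified thinning keeps all positives, subsamples negatives
            rng = np.random.default_rng(self.seed)
            pos = np.where(y == 1)[0]
            neg = np.where(y == 0)[0]
            n_neg = max(self.max_train - pos.size, pos.size)
            neg = rng.choice(neg, size=min(n_neg, neg.size), replace=False)
            keep = np.sort(np.concatenate([pos, neg]))
            x, y = x[keep], y[keep]
        self.model = svm_train(
            x, y, c_grid=self.c_grid, gamma_grid=self.gamma_grid, folds=self.folds, seed=self.seed
        )
        return self

    def score(self, x: np.ndarray) -> np.ndarray:
        assert self.model is not None, "fit before score"
        return svm_score(self.model, x)


# ---------------------------------------------------------------------------
# model persistence (JSON sidecars; the forest binary lives in `embedded`)
# ---------------------------------------------------------------------------


def forest_to_json(forest: ForestModel, path) -> None:
    payload = {
        "kind": "forest",
        "mtry": forest.mtry,
        "n_features": forest.n_features,
        "oob_error": forest.oob_error,
        "seed": forest.seed,
        "trees": [
            {
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
                "leaf_label": t.leaf_label.tolist(),
            }
            for t in forest.trees
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def forest_from_json(path) -> ForestModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "forest":
        raise InvalidInputError(f"{path} does not contain a forest model")
    trees = [
        Tree(
            feature=np.asarray(t["feature"], dtype=np.int16),
            threshold=np.asarray(t["threshold"], dtype=float),
            left=np.asarray(t["left"], dtype=np.int32),
            right=np.asarray(t["right"], dtype=np.int32),
            leaf_label=np.asarray(t["leaf_label"], dtype=np.int8),
        )
        for t in payload["trees"]
    ]
    return ForestModel(
        trees=trees,
        mtry=payload["mtry"],
        n_features=payload["n_features"],
        oob_error=payload["oob_error"],
        seed=payload["seed"],
    )


def svm_to_json(model: SvmModel, path) -> None:
    payload = {
        "kind": "svm",
        "c": model.c,
        "gamma": model.gamma,
        "cv_accuracy": model.cv_accuracy,
        "threshold": model.threshold,
        "feat_mean": model.feat_mean.tolist(),
        "feat_std": model.feat_std.tolist(),
        "support_vectors": model.svc.support_vectors_.tolist(),
        "dual_coef": model.svc.dual_coef_[0].tolist(),
        "intercept": float(model.svc.intercept_[0]),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
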