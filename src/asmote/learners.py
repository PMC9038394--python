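"""Base learners and ensembles for two-class clinical tabular data.

Implements, from first principles and with per-sample weights throughout:

* impurity functions (entropy in bits, Gini) and information gain;
* a weighted CART-style binary decision tree (``stump`` = depth 1, ``cart``
  = depth-unlimited Gini tree);
* a mixed-type naive Bayes classifier (per-class Gaussians on continuous
  columns, Laplace-smoothed frequencies on categorical ones);
* a bootstrap random forest with sqrt-feature subsampling and majority vote;
* discrete AdaBoost over any of the above as the weak learner, with the
  classic vote weight alpha_t = 0.5 * ln((1 - eps_t) / eps_t);
* heterogeneous two-member ensembles combined by (soft or hard) voting.

All randomness flows through an explicit ``numpy.random.Generator`` and all
ties (equal-gain splits, equal votes, equal posteriors, zero boosting score)
break toward the lower column index / label 0, so every learner is
bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_io import Dataset
from .errors import ConfigError, SingleClassError, UnknownModelError, ValidationError

_EPS = 1e-9


# ---------------------------------------------------------------------------
# impurity measures
# ---------------------------------------------------------------------------

def _check_fractions(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("class fractions must be nonnegative")
    if abs(p.sum() - 1.0) > _EPS:
        raise ValidationError(f"class fractions must sum to 1 (got {p.sum()})")
    return p


def entropy(p: Sequence[float]) -> float:
    """Shannon entropy in bits, -sum p log2 p with 0 log 0 := 0."""
    p = _check_fractions(np.asarray(p))
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def gini(p: Sequence[float]) -> float:
    """Gini impurity 1 - sum p_i^2."""
    p = _check_fractions(np.asarray(p))
    return float(1.0 - (p ** 2).sum())


def _impurity_fn(name: str):
    if name == "entropy":
        return entropy
    if name == "gini":
        return gini
    raise ConfigError(f"unknown impurity {name!r}")


def info_gain(parent: Sequence, left: Sequence, right: Sequence, impurity: str = "entropy") -> float:
    """Impurity decrease of splitting ``parent`` into ``left`` and ``right``.

    The child multisets must partition the parent exactly.
    """
    parent = list(parent)
    left = list(left)
    right = list(right)
    if sorted(map(str, left + right)) != sorted(map(str, parent)):
        raise ValidationError("left and right must partition the parent multiset")
    imp = _impurity_fn(impurity)

    def fractions(labels):
        labels = np.asarray(labels)
        _, counts = np.unique(labels, return_counts=True)
        return counts / counts.sum()

    n = len(parent)
    total = imp(fractions(parent))
    for child in (left, right):
        if child:
            total -= (len(child) / n) * imp(fractions(child))
    return float(total)


# ---------------------------------------------------------------------------
# weighted binary decision tree (CART-style)
# ---------------------------------------------------------------------------

def _imp_from_p1(p1: np.ndarray, criterion: str) -> np.ndarray:
    """Two-class impurity as a function of the weighted fraction of label 1."""
    p1 = np.clip(p1, 0.0, 1.0)
    q = 1.0 - p1
    if criterion == "gini":
        return 2.0 * p1 * q
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p1 > 0, p1 * np.log2(p1), 0.0) + np.where(q > 0, q * np.log2(q), 0.0))
    return h


@dataclass
class TreeNode:
    """Either an internal threshold split or a leaf with class probabilities."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    proba: tuple[float, float] | None = None  # leaf only: (P(y=0), P(y=1))

    @property
    def is_leaf(self) -> bool:
        return self.proba is not None

    @property
    def label(self) -> int:
        return 1 if self.proba[1] > self.proba[0] else 0

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


def _best_split(X, y, w, feature_ids, criterion):
    """Exhaustive scan: best (gain, feature, threshold) over midpoint thresholds.

    Tie-breaks: strictly greater gain wins, so the lowest feature index and,
    within a feature, the lowest threshold (first argmax) are preferred.
    """
    W = w.sum()
    W1 = float(w[y == 1].sum())
    parent = float(_imp_from_p1(np.array(W1 / W), criterion))
    best_gain, best_feat, best_thr = 0.0, None, None
    for j in feature_ids:
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ws = w[order]
        w1 = ws * y[order]
        cl = np.cumsum(ws)[:-1]
        cl1 = np.cumsum(w1)[:-1]
        boundary = xs[:-1] < xs[1:]
        if not boundary.any():
            continue
        cl, cl1 = cl[boundary], cl1[boundary]
        cr, cr1 = W - cl, W1 - cl1
        ok = (cl > 0) & (cr > 0)
        if not ok.any():
            continue
        cl, cl1, cr, cr1 = cl[ok], cl1[ok], cr[ok], cr1[ok]
        child = (cl * _imp_from_p1(cl1 / cl, criterion) + cr * _imp_from_p1(cr1 / cr, criterion)) / W
        gains = parent - child
        i = int(np.argmax(gains))
        if gains[i] > best_gain + 1e-15:
            mids = (xs[:-1][boundary][ok] + xs[1:][boundary][ok]) / 2.0
            best_gain, best_feat, best_thr = float(gains[i]), j, float(mids[i])
    return best_gain, best_feat, best_thr


class DecisionTree:
    """Greedy weighted binary tree; ``max_features`` enables forest-style
    per-node feature subsampling."""

    def __init__(self, max_depth=None, criterion="gini", max_features=None, min_gain=1e-12):
        _impurity_fn(criterion)
        self.max_depth = max_depth
        self.criterion = criterion
        self.max_features = max_features
        self.min_gain = min_gain
        self.root: TreeNode | None = None

    def _feature_ids(self, n_features, rng):
        if self.max_features is None or self.max_features >= n_features:
            return np.arange(n_features)
        ids = rng.choice(n_features, size=self.max_features, replace=False)
        return np.sort(ids)

    def _build(self, X, y, w, depth, rng):
        W = w.sum()
        p1 = float(w[y == 1].sum() / W)
        leaf = TreeNode(proba=(1.0 - p1, p1))
        if p1 in (0.0, 1.0) or (self.max_depth is not None and depth >= self.max_depth):
            return leaf
        gain, feat, thr = _best_split(X, y, w, self._feature_ids(X.shape[1], rng), self.criterion)
        if feat is None or gain <= self.min_gain:
            return leaf
        go_left = X[:, feat] <= thr
        node = TreeNode(feature=feat, threshold=thr)
        node.left = self._build(X[go_left], y[go_left], w[go_left], depth + 1, rng)
        node.right = self._build(X[~go_left], y[~go_left], w[~go_left], depth + 1, rng)
        return node

    def fit(self, d: Dataset, weights=None, rng=None):
        X, y = d.X, d.y
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValidationError("weights must be nonnegative with positive sum")
        if rng is None:
            rng = np.random.default_rng(0)
        keep = w > 0
        self.root = self._build(X[keep], y[keep], w[keep], 0, rng)
        return self

    def predict_proba(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))

        def descend(node, rows):
            if node.is_leaf:
                out[rows] = node.proba
                return
            go_left = X[rows, node.feature] <= node.threshold
            descend(node.left, rows[go_left])
            descend(node.right, rows[~go_left])

        descend(self.root, np.arange(X.shape[0]))
        return out

    def predict(self, X):
        p = self.predict_proba(X)
        return (p[:, 1] > p[:, 0]).astype(int)


def fit_tree(d: Dataset, weights=None, spec: "WeakLearnerSpec | None" = None) -> DecisionTree:
    """Convenience wrapper: fit a weighted tree per a :class:`WeakLearnerSpec`."""
    params = dict(spec.params) if spec is not None else {}
    return DecisionTree(**params).fit(d, weights=weights)


# ---------------------------------------------------------------------------
# naive Bayes (mixed Gaussian / categorical)
# ---------------------------------------------------------------------------

class NaiveBayes:
    """Two-stage NB: estimate per-class distribution parameters from the
    (weighted) training data, then classify by the greatest posterior.

    Continuous columns use per-class Gaussians (variance floored at 1e-9);
    categorical columns use Laplace(+1)-smoothed per-class frequencies over
    the declared category codes.  Posterior ties resolve to label 0.
    """

    def fit(self, d: Dataset, weights=None, rng=None):
        y = d.y
        if len(np.unique(y)) < 2:
            raise SingleClassError("naive Bayes requires both classes in training data")
        w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
        self.columns = d.columns
        self.log_prior = {}
        self.gauss = {}   # cls -> (means, vars) over continuous columns
        self.cat_logp = {}  # cls -> list per categorical column of {code: logp}
        self._cont = [j for j, c in enumerate(d.columns) if not c.is_categorical]
        self._cat = [j for j, c in enumerate(d.columns) if c.is_categorical]
        Wtot = w.sum()
        for cls in (0, 1):
            mask = y == cls
            wc = w[mask]
            Wc = wc.sum()
            if Wc <= 0:
                raise SingleClassError(f"class {cls} has zero total weight")
            self.log_prior[cls] = math.log(Wc / Wtot)
            if self._cont:
                Xc = d.X[mask][:, self._cont]
                mu = (wc[:, None] * Xc).sum(axis=0) / Wc
                var = (wc[:, None] * (Xc - mu) ** 2).sum(axis=0) / Wc
                self.gauss[cls] = (mu, np.maximum(var, _EPS))
            tables = []
            for j in self._cat:
                codes = np.sort(np.asarray(self.columns[j].categories))  # searchsorted needs ascending order
                counts = np.array([wc[d.X[mask, j] == c].sum() for c in codes])
                probs = (counts + 1.0) / (Wc + len(codes))
                tables.append(dict(zip(codes.tolist(), np.log(probs).tolist())))
            self.cat_logp[cls] = tables
        return self

    def _log_joint(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((X.shape[0], 2))
        for cls in (0, 1):
            lj = np.full(X.shape[0], self.log_prior[cls])
            if self._cont:
                mu, var = self.gauss[cls]
                Z = X[:, self._cont]
                lj += (-0.5 * np.log(2 * np.pi * var) - (Z - mu) ** 2 / (2 * var)).sum(axis=1)
            for tbl, j in zip(self.cat_logp[cls], self._cat):
                codes = np.array(list(tbl.keys()))
                logs = np.array(list(tbl.values()))
                # unseen-but-declared codes already smoothed; undeclared codes error
                pos = np.searchsorted(codes, X[:, j])
                pos = np.clip(pos, 0, len(codes) - 1)
                if not np.allclose(codes[pos], X[:, j]):
                    raise ValidationError(
                        f"column {self.columns[j].name!r} has codes outside the declared set"
                    )
                lj += logs[pos]
            out[:, cls] = lj
        return out

    def predict_proba(self, X):
        lj = self._log_joint(X)
        m = lj.max(axis=1, keepdims=True)
        p = np.exp(lj - m)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        lj = self._log_joint(X)
        return (lj[:, 1] > lj[:, 0]).astype(int)


def fit_nb(d: Dataset, weights=None) -> NaiveBayes:
    return NaiveBayes().fit(d, weights=weights)


def predict_nb(model: NaiveBayes, X):
    return model.predict(X), model.predict_proba(X)


# ---------------------------------------------------------------------------
# random forest
# ---------------------------------------------------------------------------

class RandomForest:
    """Bagged Gini trees with sqrt-feature subsampling and majority vote.

    Each tree trains on a size-n bootstrap resample; with per-sample weights
    the bootstrap draws indices with probability proportional to the weights
    (uniform weights recover the plain bootstrap).  The predicted class is
    the one with the most tree votes; vote fraction doubles as the class
    probability and exact ties resolve to label 0.
    """

    def __init__(self, n_trees=25, max_depth=None, bootstrap=True, max_features="sqrt"):
        if n_trees < 1:
            raise ConfigError("n_trees must be >= 1")
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.bootstrap = bootstrap
        self.max_features = max_features

    def _n_feat(self, n_features):
        if self.max_features == "sqrt":
            return max(1, int(math.sqrt(n_features)))
        if self.max_features is None:
            return n_features
        return int(self.max_features)

    def fit(self, d: Dataset, weights=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        n = d.n_samples
        w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
        p = w / w.sum()
        self.trees = []
        for _ in range(self.n_trees):
            tree = DecisionTree(
                max_depth=self.max_depth,
                criterion="gini",
                max_features=self._n_feat(d.n_features),
            )
            if self.bootstrap:
                idx = rng.choice(n, size=n, replace=True, p=p)
                boot = Dataset(
                    X=d.X[idx], y=d.y[idx], columns=list(d.columns),
                    positive_label=d.positive_label, negative_label=d.negative_label,
                    target_name=d.target_name,
                )
                tree.fit(boot, rng=rng)
            else:
                tree.fit(d, weights=w, rng=rng)
            self.trees.append(tree)
        return self

    def predict_proba(self, X):
        votes = np.stack([t.predict(X) for t in self.trees])
        frac1 = votes.mean(axis=0)
        return np.column_stack([1.0 - frac1, frac1])

    def predict(self, X):
        p = self.predict_proba(X)
        return (p[:, 1] > p[:, 0]).astype(int)


def fit_rf(d: Dataset, n_trees=25, spec=None, rng=None) -> RandomForest:
    params = dict(spec.params) if spec is not None else {}
    params.setdefault("n_trees", n_trees)
    return RandomForest(**params).fit(d, rng=rng)


def predict_rf(model: RandomForest, X):
    return model.predict(X), model.predict_proba(X)


# ---------------------------------------------------------------------------
# learner specs and factory
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeakLearnerSpec:
    """A named base-learner family plus its hyperparameters."""

    kind: str  # stump | tree | cart | nb | rf
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("stump", "tree", "cart", "nb", "rf"):
            raise UnknownModelError(f"unknown weak learner kind {self.kind!r}")


def make_learner(spec: WeakLearnerSpec):
    params = dict(spec.params)
    if spec.kind == "stump":
        params.setdefault("max_depth", 1)
        return DecisionTree(**params)
    if spec.kind in ("tree", "cart"):
        params.setdefault("criterion", "gini")
        return DecisionTree(**params)
    if spec.kind == "nb":
        return NaiveBayes(**params)
    if spec.kind == "rf":
        return RandomForest(**params)
    raise UnknownModelError(spec.kind)


# ---------------------------------------------------------------------------
# AdaBoost
# ---------------------------------------------------------------------------

@dataclass
class BoostModel:
    """Ordered (weak learner, vote weight alpha) pairs plus halt diagnostics."""

    rounds: list
    T_requested: int
    halt_reason: str | None = None
    eps: list = field(default_factory=list)
    weight_history: list = field(default_factory=list)  # D_t before each stored round, then D_{t+1}

    @property
    def T_effective(self) -> int:
        return len(self.rounds)


class AdaBoost:
    """Discrete AdaBoost with internal labels in {-1, +1}.

    Per round t: fit the weak learner on the current weight distribution D_t,
    compute the weighted error eps_t; halt discarding the round if
    eps_t >= 1/2; if eps_t = 0 store the round with the capped vote weight
    alpha = 0.5 ln((1 - eps_min)/eps_min), eps_min = 1/(2M), and halt;
    otherwise alpha_t = 0.5 ln((1 - eps_t)/eps_t) and
    D_{t+1}(i) proportional to D_t(i) exp(-alpha_t y_i h_t(x_i)), normalized
    to sum to one.
    """

    def __init__(self, weak: WeakLearnerSpec | None = None, T: int = 50):
        if T < 1:
            raise ConfigError("number of boosting rounds T must be >= 1")
        self.weak = weak if weak is not None else WeakLearnerSpec("stump")
        self.T = T
        self.model: BoostModel | None = None

    def fit(self, d: Dataset, weights=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        M = d.n_samples
        y_pm = 2 * d.y - 1
        D = np.full(M, 1.0 / M)
        rounds = []
        eps_log: list[float] = []
        history = [D.copy()]
        halt = None
        for _ in range(self.T):
            h = make_learner(self.weak)
            h.fit(d, weights=D, rng=rng)
            pred_pm = 2 * h.predict(d.X) - 1
            eps = float(D[pred_pm != y_pm].sum())
            if eps >= 0.5:
                halt = "weighted_error_at_least_half"
                break
            if eps <= 0.0:
                eps_min = 1.0 / (2.0 * M)
                rounds.append((h, 0.5 * math.log((1.0 - eps_min) / eps_min)))
                eps_log.append(eps)
                halt = "perfect_weak_learner"
                break
            alpha = 0.5 * math.log((1.0 - eps) / eps)
            rounds.append((h, alpha))
            eps_log.append(eps)
            D = D * np.exp(-alpha * y_pm * pred_pm)
            D = D / D.sum()
            history.append(D.copy())
        self.model = BoostModel(rounds=rounds, T_requested=self.T, halt_reason=halt,
                                eps=eps_log, weight_history=history)
        return self

    def decision_scores(self, X):
        if self.model is None or not self.model.rounds:
            raise SingleClassError("boosting model has no usable round")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        score = np.zeros(X.shape[0])
        for h, alpha in self.model.rounds:
            score += alpha * (2 * h.predict(X) - 1)
        return score

    def predict(self, X):
        return (self.decision_scores(X) > 0).astype(int)

    def predict_proba(self, X):
        """Logistic squashing of the additive score — a monotone surrogate
        probability used only for soft voting."""
        s = self.decision_scores(X)
        p1 = 1.0 / (1.0 + np.exp(-2.0 * s))
        return np.column_stack([1.0 - p1, p1])


def adaboost_fit(d: Dataset, weak: WeakLearnerSpec | None = None, T: int = 50,
                 rng=None) -> AdaBoost:
    return AdaBoost(weak=weak, T=T).fit(d, rng=rng)


def adaboost_predict(model: AdaBoost, X):
    return model.predict(X), model.decision_scores(X)


# ---------------------------------------------------------------------------
# heterogeneous pair ensemble
# ---------------------------------------------------------------------------

class PairEnsemble:
    """Two different base-learner families fitted on identical data and
    combined by voting (default: equal-weight soft vote on class
    probabilities; hard vote optional).  Ties resolve to label 0."""

    def __init__(self, spec1: WeakLearnerSpec, spec2: WeakLearnerSpec, combine="soft"):
        if spec1.kind == spec2.kind:
            raise ConfigError("pair members must be of different kinds")
        if combine not in ("soft", "hard"):
            raise ConfigError(f"unknown combination rule {combine!r}")
        self.spec1, self.spec2, self.combine = spec1, spec2, combine

    def fit(self, d: Dataset, weights=None, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.members = []
        for spec in (self.spec1, self.spec2):
            m = make_learner(spec)
            m.fit(d, weights=weights, rng=rng)
            self.members.append(m)
        return self

    def predict_proba(self, X):
        if self.combine == "soft":
            return np.mean([m.predict_proba(X) for m in self.members], axis=0)
        votes1 = np.mean([m.predict(X) for m in self.members], axis=0)
        return np.column_stack([1.0 - votes1, votes1])

    def predict(self, X):
        p = self.predict_proba(X)
        return (p[:, 1] > p[:, 0]).astype(int)


def pair_fit(d: Dataset, spec1: WeakLearnerSpec, spec2: WeakLearnerSpec,
             combine="soft", rng=None) -> PairEnsemble:
    return PairEnsemble(spec1, spec2, combine=combine).fit(d, rng=rng)


def pair_predict(model: PairEnsemble, X):
    return model.predict(X)


# ---------------------------------------------------------------------------
# model-name vocabulary (mirrors the comparison-table naming)
# ---------------------------------------------------------------------------

_BASE_NAMES = {
    "nb": WeakLearnerSpec("nb"),
    "cart": WeakLearnerSpec("cart"),
    "rf": WeakLearnerSpec("rf"),
    "stump": WeakLearnerSpec("stump"),
}


def build_model(name: str, T: int = 50, combine: str = "soft"):
    """Instantiate a model from its grid name.

    Accepted: base names ``nb``, ``cart``, ``rf``, ``stump``; AdaBoost
    homogeneous ensembles ``ab-nb``, ``ab-cart``, ``ab-rf``, ``ab-stump``;
    heterogeneous pairs like ``rf+cart`` or ``nb+rf``.
    """
    name = name.strip().lower()
    if name in _BASE_NAMES:
        return make_learner(_BASE_NAMES[name])
    if name.startswith("ab-"):
        base = name[3:]
        if base not in _BASE_NAMES:
            raise UnknownModelError(f"unknown AdaBoost base {base!r}")
        return AdaBoost(weak=_BASE_NAMES[base], T=T)
    if "+" in name:
        a, b = (s.strip() for s in name.split("+", 1))
        if a not in _BASE_NAMES or b not in _BASE_NAMES:
            raise UnknownModelError(f"unknown pair members in {name!r}")
        return PairEnsemble(_BASE_NAMES[a], _BASE_NAMES[b], combine=combine)
    raise UnknownModelError(f"unknown model name {name!r}")
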