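import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asmote import (
    AdaBoost,
    ColumnSpec,
    Dataset,
    DecisionTree,
    NaiveBayes,
    PairEnsemble,
    RandomForest,
    WeakLearnerSpec,
    build_model,
    entropy,
    gini,
    info_gain,
)
from asmote.errors import ConfigError, SingleClassError, UnknownModelError, ValidationError
from asmote.learners import fit_tree

CONT1 = [ColumnSpec("x", "continuous")]
CONT2 = [ColumnSpec("a", "continuous"), ColumnSpec("b", "continuous")]


def _ds(X, y, columns=None):
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != len(y):
        X = X.T
    cols = columns or [ColumnSpec(f"f{j}", "continuous") for j in range(X.shape[1])]
    return Dataset(X=X, y=np.asarray(y, int), columns=cols)


simplex2 = st.floats(min_value=0.0, max_value=1.0).map(lambda p: (p, 1.0 - p))


class TestImpurity:
    @pytest.mark.parametrize("p,expected", [
        ((0.5, 0.5), 1.0), ((1.0, 0.0), 0.0), ((0.25, 0.75), 0.8112781244591328),
    ])
    def test_entropy_values(self, p, expected):
        assert entropy(p) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("p,expected", [
        ((0.5, 0.5), 0.5), ((1.0, 0.0), 0.0), ((0.3, 0.7), 0.42),
    ])
    def test_gini_values(self, p, expected):
        assert gini(p) == pytest.approx(expected, abs=1e-12)

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValidationError):
            entropy((0.5, 0.6))
        with pytest.raises(ValidationError):
            gini((-0.1, 1.1))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(simplex2)
    def test_maximal_at_uniform_zero_at_pure(self, p):
        assert 0.0 <= entropy(p) <= entropy((0.5, 0.5)) + 1e-12
        assert 0.0 <= gini(p) <= gini((0.5, 0.5)) + 1e-12


class TestInfoGain:
    def test_pure_children_give_one_bit(self):
        assert info_gain([0, 0, 1, 1], [0, 0], [1, 1], "entropy") == pytest.approx(1.0)

    def test_empty_right_child_gains_nothing(self):
        assert info_gain([0, 1, 1], [0, 1, 1], [], "entropy") == pytest.approx(0.0)

    def test_partition_mismatch_errors(self):
        with pytest.raises(ValidationError):
            info_gain([0, 0, 1], [0], [1])

    @pytest.mark.parametrize("impurity", ["entropy", "gini"])
    def test_nonnegative_and_matches_recomputation(self, impurity, rng):
        imp = entropy if impurity == "entropy" else gini
        for _ in range(30):
            labels = rng.integers(0, 2, size=int(rng.integers(2, 15)))
            cut = int(rng.integers(0, len(labels) + 1))
            left, right = labels[:cut], labels[cut:]

            def frac(ls):
                p1 = np.mean(ls == 1) if len(ls) else 0.0
                return (1 - p1, p1)

            expected = imp(frac(labels))
            for child in (left, right):
                if len(child):
                    expected -= len(child) / len(labels) * imp(frac(child))
            got = info_gain(labels.tolist(), left.tolist(), right.tolist(), impurity)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got >= -1e-12


class TestDecisionTree:
    def test_separable_stump(self):
        d = _ds([1, 2, 8, 9], [0, 0, 1, 1], CONT1)
        t = DecisionTree(max_depth=1).fit(d)
        assert 2 < t.root.threshold < 8
        assert (t.predict(d.X) == d.y).all()

    def test_pure_input_yields_single_leaf(self):
        d = _ds([1, 2, 3], [1, 1, 1], CONT1)
        t = DecisionTree().fit(d)
        assert t.root.is_leaf and t.root.label == 1

    def test_depth_one_split_matches_exhaustive_search(self, rng):
        for trial in range(10):
            X = rng.normal(size=(20, 2))
            y = rng.integers(0, 2, size=20)
            if len(np.unique(y)) < 2:
                continue
            d = _ds(X, y, CONT2)
            t = DecisionTree(max_depth=1, criterion="gini").fit(d)

            def weighted_gini(labels):
                if len(labels) == 0:
                    return 0.0
                p1 = np.mean(labels)
                return 2 * p1 * (1 - p1)

            best_gain, best = 0.0, None
            parent = weighted_gini(y)
            for j in range(2):
                vals = np.unique(X[:, j])
                for lo, hi in zip(vals[:-1], vals[1:]):
                    thr = (lo + hi) / 2
                    m = X[:, j] <= thr
                    gain = parent - (m.mean() * weighted_gini(y[m])
                                     + (~m).mean() * weighted_gini(y[~m]))
                    if gain > best_gain + 1e-15:
                        best_gain, best = gain, (j, thr)
            if best is None:
                assert t.root.is_leaf
            else:
                assert (t.root.feature, t.root.threshold) == pytest.approx(best)

    def test_weighting_moves_the_split(self):
        # upweighting the lone right-side 0 makes it worth isolating
        d = _ds([0, 1, 2, 3], [0, 1, 1, 0], CONT1)
        w_uniform = np.ones(4)
        w_boosted = np.array([1.0, 1.0, 1.0, 10.0])
        t1 = fit_tree(d, weights=w_uniform, spec=WeakLearnerSpec("stump"))
        t2 = fit_tree(d, weights=w_boosted, spec=WeakLearnerSpec("stump"))
        assert t2.predict([[3.0]])[0] == 0
        assert t1.root.threshold != t2.root.threshold

    def test_all_zero_weights_error(self):
        d = _ds([0, 1], [0, 1], CONT1)
        with pytest.raises(ValidationError):
            DecisionTree().fit(d, weights=np.zeros(2))

    def test_matches_sklearn_on_separable_data(self, separable):
        sk = pytest.importorskip("sklearn.tree")
        ours = DecisionTree(max_depth=3).fit(separable)
        ref = sk.DecisionTreeClassifier(max_depth=3, random_state=0)
        ref.fit(separable.X, separable.y)
        ours_acc = (ours.predict(separable.X) == separable.y).mean()
        ref_acc = ref.score(separable.X, separable.y)
        assert ours_acc == pytest.approx(ref_acc, abs=0.02)


class TestNaiveBayes:
    def test_separated_gaussians(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        y = np.array([0] * 50 + [1] * 50)
        nb = NaiveBayes().fit(_ds(x, y, CONT1))
        assert nb.predict([[1.0]])[0] == 0
        assert nb.predict([[9.0]])[0] == 1

    def test_hand_computed_categorical_posterior(self):
        # 3 rows, one binary code; Laplace(+1) smoothing by hand:
        # P(y=1|x=1) = (1/3 * 2/3) / (1/3 * 2/3 + 2/3 * 1/4) = 4/7
        cols = [ColumnSpec("c", "categorical", (0.0, 1.0))]
        nb = NaiveBayes().fit(_ds([[0.0], [0.0], [1.0]], [0, 0, 1], cols))
        p = nb.predict_proba([[1.0]])[0]
        assert p[1] == pytest.approx(4 / 7, abs=1e-12)
        assert nb.predict([[1.0]])[0] == 1

    def test_midpoint_tie_resolves_to_label_zero(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        nb = NaiveBayes().fit(_ds(x, [0, 0, 1, 1], CONT1))
        assert nb.predict([[0.0]])[0] == 0

    def test_single_class_errors(self):
        with pytest.raises(SingleClassError):
            NaiveBayes().fit(_ds([1, 2], [1, 1], CONT1))


class TestRandomForest:
    def test_single_tree_without_bootstrap_equals_plain_tree(self, separable):
        rf = RandomForest(n_trees=1, bootstrap=False, max_features=None)
        rf.fit(separable, rng=np.random.default_rng(3))
        tree = DecisionTree().fit(separable, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(rf.predict(separable.X), tree.predict(separable.X))

    def test_training_accuracy_one_on_separable(self, separable):
        rf = RandomForest(n_trees=50).fit(separable, rng=np.random.default_rng(0))
        assert (rf.predict(separable.X) == separable.y).mean() == 1.0

    def test_deterministic_given_seed(self, overlapping):
        p1 = RandomForest(n_trees=10).fit(overlapping, rng=np.random.default_rng(9)).predict(overlapping.X)
        p2 = RandomForest(n_trees=10).fit(overlapping, rng=np.random.default_rng(9)).predict(overlapping.X)
        np.testing.assert_array_equal(p1, p2)

    def test_invalid_tree_count(self):
        with pytest.raises(ConfigError):
            RandomForest(n_trees=0)


class TestAdaBoost:
    def test_reweighted_error_of_each_round_is_half(self, overlapping):
        ab = AdaBoost(T=10).fit(overlapping)
        m = ab.model
        assert m.T_effective >= 2
        y_pm = 2 * overlapping.y - 1
        for t, (h, _) in enumerate(m.rounds):
            if t + 1 >= len(m.weight_history):
                break  # final round has no successor distribution
            D_next = m.weight_history[t + 1]
            pred = 2 * h.predict(overlapping.X) - 1
            assert D_next[pred != y_pm].sum() == pytest.approx(0.5, abs=1e-9)
            assert D_next.sum() == pytest.approx(1.0, abs=1e-12)

    def test_known_weighted_error_gives_half_ln_four(self):
        # every depth-1 split of this set errs exactly one of five points
        d = _ds([0, 1, 2, 3, 10], [0, 0, 1, 0, 1], CONT1)
        ab = AdaBoost(T=1).fit(d)
        assert ab.model.eps[0] == pytest.approx(0.2)
        assert ab.model.rounds[0][1] == pytest.approx(0.5 * math.log(4), abs=1e-9)

    def test_chance_level_first_round_halts_with_empty_model(self):
        # XOR labels: no stump beats chance, the round is rejected
        d = _ds([[0, 0], [0, 1], [1, 0], [1, 1]], [0, 1, 1, 0], CONT2)
        ab = AdaBoost(T=5).fit(d)
        assert ab.model.T_effective == 0
        assert ab.model.halt_reason == "weighted_error_at_least_half"
        with pytest.raises(SingleClassError):
            ab.predict(d.X)

    def test_perfect_weak_learner_caps_alpha_and_halts(self):
        d = _ds([1, 2, 8, 9], [0, 0, 1, 1], CONT1)
        ab = AdaBoost(T=10).fit(d)
        m = ab.model
        assert m.halt_reason == "perfect_weak_learner" and m.T_effective == 1
        eps_min = 1 / (2 * 4)
        assert m.rounds[0][1] == pytest.approx(0.5 * math.log((1 - eps_min) / eps_min))

    def test_single_round_reduces_to_weak_learner(self, overlapping):
        ab = AdaBoost(T=1).fit(overlapping)
        stump = DecisionTree(max_depth=1).fit(overlapping)
        np.testing.assert_array_equal(ab.predict(overlapping.X), stump.predict(overlapping.X))

    def test_training_error_bounded_by_product(self, overlapping):
        ab = AdaBoost(T=15).fit(overlapping)
        train_err = (ab.predict(overlapping.X) != overlapping.y).mean()
        bound = np.prod([2 * math.sqrt(e * (1 - e)) for e in ab.model.eps if e > 0])
        assert train_err <= bound + 1e-12

    def test_label_flip_antisymmetry(self, separable):
        flipped = Dataset(X=separable.X.copy(), y=1 - separable.y,
                          columns=list(separable.columns))
        a = AdaBoost(T=10).fit(separable, rng=np.random.default_rng(1))
        b = AdaBoost(T=10).fit(flipped, rng=np.random.default_rng(1))
        pa, pb = a.predict(separable.X), b.predict(separable.X)
        np.testing.assert_array_equal(pa, 1 - pb)

    def test_invalid_rounds(self):
        with pytest.raises(ConfigError):
            AdaBoost(T=0)


class _Stub:
    def __init__(self, proba):
        self._p = np.asarray(proba, float)

    def predict_proba(self, X):
        return self._p

    def predict(self, X):
        return (self._p[:, 1] > self._p[:, 0]).astype(int)


class TestPairEnsemble:
    def _pair(self, p1, p2, combine="soft"):
        pe = PairEnsemble(WeakLearnerSpec("nb"), WeakLearnerSpec("rf"), combine=combine)
        pe.members = [_Stub(p1), _Stub(p2)]
        return pe

    def test_agreeing_members_equal_either(self):
        pe = self._pair([[0.9, 0.1]], [[0.8, 0.2]])
        assert pe.predict(np.zeros((1, 2)))[0] == 0

    def test_soft_vote_arithmetic(self):
        pe = self._pair([[0.9, 0.1]], [[0.2, 0.8]])
        np.testing.assert_allclose(pe.predict_proba(None)[0], [0.55, 0.45])
        assert pe.predict(np.zeros((1, 2)))[0] == 0

    def test_symmetric_disagreement_ties_to_label_zero(self):
        pe = self._pair([[0.6, 0.4]], [[0.4, 0.6]])
        assert pe.predict(np.zeros((1, 2)))[0] == 0

    def test_hard_vote_tie_resolves_to_zero(self):
        pe = self._pair([[0.9, 0.1]], [[0.1, 0.9]], combine="hard")
        assert pe.predict(np.zeros((1, 2)))[0] == 0

    def test_identical_kinds_rejected(self):
        with pytest.raises(ConfigError):
            PairEnsemble(WeakLearnerSpec("rf"), WeakLearnerSpec("rf"))

    def test_fitted_pair_on_real_data(self, separable):
        pe = PairEnsemble(WeakLearnerSpec("nb"), WeakLearnerSpec("stump"))
        pe.fit(separable, rng=np.random.default_rng(0))
        assert (pe.predict(separable.X) == separable.y).mean() > 0.9


class TestModelVocabulary:
    @pytest.mark.parametrize("name,cls", [
        ("nb", NaiveBayes), ("cart", DecisionTree), ("rf", RandomForest),
        ("ab-rf", AdaBoost), ("ab-nb", AdaBoost), ("ab-cart", AdaBoost),
        ("rf+cart", PairEnsemble), ("nb+rf", PairEnsemble),
    ])
    def test_accepted_names(self, name, cls):
        assert isinstance(build_model(name), cls)

    @pytest.mark.parametrize("name", ["svm", "ab-svm", "rf+rf", "nb+xgb"])
    def test_rejected_names(self, name):
        with pytest.raises((UnknownModelError, ConfigError)):
            build_model(name)
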