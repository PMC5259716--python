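"""The six classifier families: contracts, missing-value handling, oracles."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from conftest import gaussian_task
from toxmark.estimators import (
    ALGORITHMS,
    AdaBoostM1Classifier,
    BaggingTreesClassifier,
    C45TreeClassifier,
    GaussianNBMissing,
    KNNMissingClassifier,
    RandomForestMissingClassifier,
    deserialize_model,
    make_classifier,
    serialize_model,
)


def _xy(fm):
    return fm.values, fm.label_array


class TestC45Tree:
    def test_separable_single_split(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array(["NGHC", "NGHC", "NHC", "NHC"])
        model = C45TreeClassifier().fit(X, y)
        assert 2 < model.root_.threshold < 8
        assert model.predict_score(np.array([[0.0]]))[0] == 1.0
        assert model.predict_score(np.array([[10.0]]))[0] == 0.0

    def test_single_class_training_gives_constant_score(self):
        X = np.array([[1.0], [2.0], [3.0]])
        model = C45TreeClassifier().fit(X, np.array(["NGHC"] * 3))
        assert model.root_.is_leaf
        np.testing.assert_allclose(model.predict_score(X), 1.0)

    @staticmethod
    def _two_level_tree():
        """Root must split f0 (informative); f1 refines within each side."""
        rows, labels = [], []
        # left of f0: 6 NGHC at f1=0, 2 NHC at f1=10 -> 8 samples
        rows += [[0.0, 0.0]] * 6 + [[0.0, 10.0]] * 2
        labels += ["NGHC"] * 6 + ["NHC"] * 2
        # right of f0: 3 NHC at f1=0, 1 NGHC at f1=10 -> 4 samples
        rows += [[10.0, 0.0]] * 3 + [[10.0, 10.0]] * 1
        labels += ["NHC"] * 3 + ["NGHC"] * 1
        return C45TreeClassifier().fit(np.array(rows), np.array(labels))

    def test_missing_root_feature_mixes_branches(self):
        """A row missing the split feature scores the branch-weighted mixture."""
        model = self._two_level_tree()
        root = model.root_
        assert not root.is_leaf and root.feature == 0
        left_score = model.predict_score(np.array([[0.0, 0.0]]))[0]
        right_score = model.predict_score(np.array([[10.0, 0.0]]))[0]
        expected = (root.w_left * left_score + root.w_right * right_score) / (
            root.w_left + root.w_right
        )
        got = model.predict_score(np.array([[np.nan, 0.0]]))[0]
        assert got == pytest.approx(expected)
        assert got == pytest.approx((8 * left_score + 4 * right_score) / 12)

    def test_missing_values_during_fit_tolerated(self):
        fm = gaussian_task(missing_rate=0.3, seed=2)
        X, y = _xy(fm)
        model = C45TreeClassifier().fit(X, y)
        scores = model.predict_score(X)
        assert np.all((scores >= 0) & (scores <= 1))

    def test_prediction_row_order_independent(self):
        fm = gaussian_task(seed=4)
        X, y = _xy(fm)
        model = C45TreeClassifier().fit(X, y)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(
            model.predict_score(X)[perm], model.predict_score(X[perm])
        )


class TestEnsembles:
    def test_bagging_single_tree_no_bootstrap_reduces_to_tree(self):
        fm = gaussian_task(n_pos=20, n_neg=40, sd=1.0, seed=5)
        X, y = _xy(fm)
        bag = BaggingTreesClassifier(n_trees=1, bootstrap=False).fit(X, y)
        tree = C45TreeClassifier().fit(X, y)
        np.testing.assert_allclose(bag.predict_score(X), tree.predict_score(X))

    def test_bagging_score_granularity_on_separable_task(self, separable_fm):
        X, y = _xy(separable_fm)
        bag = BaggingTreesClassifier(n_trees=15, random_state=1).fit(X, y)
        scores = bag.predict_score(np.array([[0.0], [12.0]]))
        # pure leaves -> scores are vote fractions in {0,...,15}/15
        assert all(round(s * 15, 8) == round(s * 15) for s in scores)
        assert scores[0] == 1.0 and scores[1] == 0.0

    def test_random_forest_candidate_feature_rule(self):
        assert RandomForestMissingClassifier.n_candidate_features(4) == 3
        assert RandomForestMissingClassifier.n_candidate_features(23) == 5
        assert RandomForestMissingClassifier.n_candidate_features(1) == 1

    def test_ensemble_prefix_property(self):
        """The first 10 members of a 20-tree ensemble equal the 10-tree fit."""
        fm = gaussian_task(n_pos=25, n_neg=50, sd=1.0, seed=6)
        X, y = _xy(fm)
        small = BaggingTreesClassifier(n_trees=10, random_state=3).fit(X, y)
        big = BaggingTreesClassifier(n_trees=20, random_state=3).fit(X, y)
        for a, b in zip(small.trees_, big.trees_[:10]):
            assert (a.feature, a.threshold) == (b.feature, b.threshold)

    def test_boosting_early_stop_on_perfect_member(self, separable_fm):
        X, y = _xy(separable_fm)
        model = AdaBoostM1Classifier(n_trees=25).fit(X, y)
        assert len(model.trees_) == 1  # first round already has zero error
        assert model.predict_score(np.array([[0.0]]))[0] == 1.0

    def test_bagging_reduces_score_variance(self):
        """Across data redraws of a fixed noisy task, bagged AUC varies no
        more than a lone tree's (variance reduction needs the base learner
        off the chance floor, hence a moderately separable task)."""
        tree_aucs, bag_aucs = [], []
        for seed in range(20):
            train = gaussian_task(n_pos=30, n_neg=90, shift=-1.0, sd=0.7, seed=seed)
            test = gaussian_task(
                n_pos=100, n_neg=300, shift=-1.0, sd=0.7, seed=1000 + seed
            )
            Xtr, ytr = _xy(train)
            Xte, yte = _xy(test)
            tree = C45TreeClassifier().fit(Xtr, ytr)
            bag = BaggingTreesClassifier(n_trees=25, random_state=seed).fit(Xtr, ytr)
            tree_aucs.append(roc_auc_score(yte == "NGHC", tree.predict_score(Xte)))
            bag_aucs.append(roc_auc_score(yte == "NGHC", bag.predict_score(Xte)))
        assert np.std(bag_aucs, ddof=1) <= np.std(tree_aucs, ddof=1)


class TestNaiveBayes:
    def test_symmetric_midpoint_scores_half(self):
        X = np.array([[-2.0], [-1.0], [-1.5], [2.0], [1.0], [1.5]])
        y = np.array(["NGHC"] * 3 + ["NHC"] * 3)
        model = GaussianNBMissing().fit(X, y)
        assert model.predict_score(np.array([[0.0]]))[0] == pytest.approx(0.5)

    def test_all_features_missing_scores_prior(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0], [7.0], [8.5]])
        y = np.array(["NGHC"] * 2 + ["NHC"] * 4)
        model = GaussianNBMissing().fit(X, y)
        assert model.predict_score(np.array([[np.nan]]))[0] == pytest.approx(2 / 6)

    def test_well_separated_classes_confident_at_class_mean(self):
        rng = np.random.default_rng(1)
        X = np.vstack(
            [rng.normal(0, 0.5, size=(30, 2)), rng.normal(8, 0.5, size=(30, 2))]
        )
        y = np.array(["NGHC"] * 30 + ["NHC"] * 30)
        model = GaussianNBMissing().fit(X, y)
        assert model.predict_score(X[:5].mean(0, keepdims=True))[0] > 0.99

    def test_sparse_class_feature_skipped_not_fatal(self):
        X = np.array([[1.0, np.nan], [2.0, np.nan], [8.0, 3.0], [9.0, 4.0], [7.0, 5.0]])
        y = np.array(["NGHC", "NGHC", "NHC", "NHC", "NHC"])
        model = GaussianNBMissing().fit(X, y)
        # class index 1 is the positive class (NGHC): no observations there
        assert np.isnan(model.theta_[1, 1])
        s = model.predict_score(np.array([[1.5, 4.0]]))[0]
        assert 0 <= s <= 1


class TestKNN:
    def test_self_match_k1(self):
        fm = gaussian_task(n_pos=10, n_neg=20, seed=7)
        X, y = _xy(fm)
        model = KNNMissingClassifier(k=1).fit(X, y)
        preds = model.predict(X)
        np.testing.assert_array_equal(preds, y)

    def test_vote_fraction_k3(self):
        X = np.array([[0.0], [0.1], [0.2], [5.0]])
        y = np.array(["NGHC", "NGHC", "NHC", "NHC"])
        model = KNNMissingClassifier(k=3).fit(X, y)
        assert model.predict_score(np.array([[0.05]]))[0] == pytest.approx(2 / 3)

    def test_distance_rescaling_with_missing(self):
        # query observes 1 of 2 features: distance = sqrt(2/1 * d^2)
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        y = np.array(["NGHC", "NHC"])
        model = KNNMissingClassifier(k=1).fit(X, y)
        d = model._distances(np.array([1.0, np.nan]))
        assert d[0] == pytest.approx(np.sqrt(2 * 1.0))
        assert d[1] == pytest.approx(np.sqrt(2 * 4.0))

    def test_unreachable_pair_infinite_distance(self):
        X = np.array([[np.nan, 1.0], [2.0, np.nan]])
        y = np.array(["NGHC", "NHC"])
        model = KNNMissingClassifier(k=1).fit(X, y)
        d = model._distances(np.array([np.nan, np.nan]))
        assert np.isinf(d).all()

    def test_tie_breaks_by_training_order(self):
        X = np.array([[0.0], [0.0], [9.0]])
        y = np.array(["NHC", "NGHC", "NGHC"])
        model = KNNMissingClassifier(k=1).fit(X, y)
        # both first rows at distance 0; earliest training row wins
        assert model.predict(np.array([[0.0]]))[0] == "NHC"

    def test_k_larger_than_n_rejected(self):
        from toxmark.errors import ConfigError

        with pytest.raises(ConfigError):
            KNNMissingClassifier(k=5).fit(np.zeros((3, 1)), np.array(["a", "b", "a"]))


@pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
def test_thirty_percent_missing_contract(algorithm):
    """Every family trains and scores a 30%-missing matrix without error."""
    fm = gaussian_task(n_pos=25, n_neg=60, missing_rate=0.3, seed=9)
    X, y = _xy(fm)
    model = make_classifier(algorithm)
    model.fit(X, y)
    scores = model.predict_score(X)
    assert scores.shape == (85,)
    assert np.all((scores >= 0) & (scores <= 1))
    assert np.isfinite(scores).all()


_SKLEARN_TWINS = {
    "tree": DecisionTreeClassifier(random_state=0),
    "bagging": BaggingClassifier(DecisionTreeClassifier(), n_estimators=25, random_state=0),
    "boosting": AdaBoostClassifier(n_estimators=25, random_state=0),
    "random_forest": RandomForestClassifier(n_estimators=25, random_state=0),
    "naive_bayes": GaussianNB(),
    "knn": KNeighborsClassifier(n_neighbors=3),
}
_OURS = {
    "tree": C45TreeClassifier(),
    "bagging": BaggingTreesClassifier(n_trees=25, random_state=0),
    "boosting": AdaBoostM1Classifier(n_trees=25),
    "random_forest": RandomForestMissingClassifier(n_trees=25, random_state=0),
    "naive_bayes": GaussianNBMissing(),
    "knn": KNNMissingClassifier(k=3),
}


@pytest.mark.parametrize("algorithm", sorted(_OURS))
def test_family_agreement_with_reference_implementation(algorithm):
    """On complete, well-separated data each family tracks its sklearn
    counterpart's AUC (high-variance families need a clean task for a
    family-level comparison to be meaningful)."""
    train = gaussian_task(n_pos=50, n_neg=150, shift=-2.0, sd=0.6, seed=21)
    test = gaussian_task(n_pos=50, n_neg=150, shift=-2.0, sd=0.6, seed=22)
    Xtr, ytr = _xy(train)
    Xte, yte = _xy(test)
    ours = clone(_OURS[algorithm]).fit(Xtr, ytr)
    auc_ours = roc_auc_score(yte == "NGHC", ours.predict_score(Xte))
    ref = clone(_SKLEARN_TWINS[algorithm]).fit(Xtr, ytr == "NGHC")
    auc_ref = roc_auc_score(yte == "NGHC", ref.predict_proba(Xte)[:, 1])
    assert abs(auc_ours - auc_ref) < 0.05


@pytest.mark.parametrize("algorithm", sorted(ALGORITHMS))
def test_serialization_round_trip(algorithm):
    fm = gaussian_task(n_pos=15, n_neg=30, missing_rate=0.1, seed=13)
    X, y = _xy(fm)
    model = make_classifier(algorithm).fit(X, y)
    import json

    doc = json.loads(json.dumps(serialize_model(model)))
    restored = deserialize_model(doc)
    np.testing.assert_allclose(restored.predict_score(X), model.predict_score(X))


def test_sklearn_clone_compatibility():
    model = BaggingTreesClassifier(n_trees=7, random_state=5)
    cloned = clone(model)
    assert cloned.get_params() == model.get_params()
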