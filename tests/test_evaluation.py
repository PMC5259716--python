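"""ROC/AUC, LOOCV, tuning and the platform-matched independent test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gaussian_task, small_study_config
from toxmark.data import feature_matrix
from toxmark.errors import ConfigError, InsufficientDataError
from toxmark.estimators import (
    BaggingTreesClassifier,
    GaussianNBMissing,
    KNNMissingClassifier,
)
from toxmark.evaluation import (
    DatasetModel,
    ScoreSet,
    independent_test,
    loocv,
    roc_auc,
    tune,
)
from toxmark.simulate import CODELINK_LIKE, generate_independent_set, generate_study


def pair_count_auc(scores, labels, positive="NGHC"):
    """Brute-force all-pairs oracle: wins + half-ties over pos×neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l == positive]
    neg = [s for s, l in zip(scores, labels) if l != positive]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def _scoreset(scores, labels):
    return ScoreSet([f"c{i}" for i in range(len(scores))], np.array(scores), np.array(labels))


class TestRocAuc:
    def test_perfect_ranking(self):
        ss = _scoreset([0.9, 0.8, 0.2, 0.1], ["NGHC", "NGHC", "NHC", "NHC"])
        assert roc_auc(ss).auc == 1.0

    def test_interleaved_example(self):
        # one win, one loss of two pairs
        ss = _scoreset([0.9, 0.8, 0.85], ["NGHC", "NGHC", "NHC"])
        assert roc_auc(ss).auc == 0.5

    def test_all_tied(self):
        ss = _scoreset([0.5] * 6, ["NGHC", "NHC"] * 3)
        assert roc_auc(ss).auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(InsufficientDataError):
            roc_auc(_scoreset([0.1, 0.2], ["NGHC", "NGHC"]))

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        ss = _scoreset(
            rng.random(30).round(1), ["NGHC"] * 10 + ["NHC"] * 20
        )
        curve = roc_auc(ss).curve
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve, axis=0) >= 0).all()

    def test_matches_pair_count_oracle_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(4, 25))
            labels = ["NGHC"] * int(rng.integers(1, n - 1))
            labels += ["NHC"] * (n - len(labels))
            # coarse grid forces heavy ties
            scores = rng.integers(0, 4, size=n) / 3.0
            ss = _scoreset(scores, labels)
            assert roc_auc(ss).auc == pytest.approx(
                pair_count_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(40)
        labels = ["NGHC"] * 15 + ["NHC"] * 25
        a = roc_auc(_scoreset(scores, labels)).auc
        b = roc_auc(_scoreset(1 / (1 + np.exp(-7 * scores)), labels)).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 5, size=30) / 4.0
        labels = ["NGHC"] * 12 + ["NHC"] * 18
        a = roc_auc(_scoreset(scores, labels)).auc
        b = roc_auc(_scoreset(1.0 - scores, labels)).auc
        assert a == pytest.approx(1.0 - b, abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(st.integers(0, 5), min_size=2, max_size=15),
    st.lists(st.integers(0, 5), min_size=2, max_size=15),
)
def test_roc_auc_pair_count_property(pos_scores, neg_scores):
    scores = [s / 5 for s in pos_scores + neg_scores]
    labels = ["NGHC"] * len(pos_scores) + ["NHC"] * len(neg_scores)
    assert roc_auc(_scoreset(scores, labels)).auc == pytest.approx(
        pair_count_auc(scores, labels), abs=1e-12
    )


class TestLoocv:
    def test_fold_count(self):
        fm = gaussian_task(n_pos=4, n_neg=6, seed=1)
        ss = loocv(fm, KNNMissingClassifier(k=1))
        assert len(ss.scores) == 10

    def test_duplicate_rows_decide_one_nn(self):
        # each chemical's nearest neighbour is its duplicate in the other class
        values = np.array([[1.0], [1.0], [5.0], [5.0], [9.0], [9.0]])
        labels = ["NGHC", "NHC", "NGHC", "NHC", "NGHC", "NHC"]
        chems = [f"c{i}" for i in range(6)]
        from toxmark.data import FeatureMatrix

        fm = FeatureMatrix(chems, ["g0"], values, dict(zip(chems, labels)))
        ss = loocv(fm, KNNMissingClassifier(k=1))
        for i, lab in enumerate(labels):
            dup_label = labels[i - 1] if i % 2 else labels[i + 1]
            assert ss.scores[i] == (1.0 if dup_label == "NGHC" else 0.0)

    def test_deterministic_for_deterministic_algorithms(self):
        fm = gaussian_task(n_pos=8, n_neg=12, seed=3)
        a = loocv(fm, GaussianNBMissing())
        b = loocv(fm, GaussianNBMissing())
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_no_leakage_from_heldout_label(self):
        """Flipping the held-out chemical's label never moves its own score."""
        fm = gaussian_task(n_pos=6, n_neg=9, seed=4)
        ss = loocv(fm, KNNMissingClassifier(k=3))
        flipped_labels = dict(fm.labels)
        target = fm.chemicals[0]
        flipped_labels[target] = "NHC" if fm.labels[target] == "NGHC" else "NGHC"
        from toxmark.data import FeatureMatrix

        fm2 = FeatureMatrix(fm.chemicals, fm.features, fm.values, flipped_labels)
        ss2 = loocv(fm2, KNNMissingClassifier(k=3))
        assert ss.scores[0] == ss2.scores[0]

    def test_minimum_size_enforced(self):
        fm = gaussian_task(n_pos=1, n_neg=1, seed=5)
        with pytest.raises(ConfigError):
            loocv(fm, GaussianNBMissing())

    def test_single_member_class_folds_flagged(self):
        fm = gaussian_task(n_pos=1, n_neg=4, seed=6)
        ss = loocv(fm, GaussianNBMissing())
        assert fm.chemicals[0] in ss.flagged
        assert ss.scores[0] == 0.0  # training prior of NGHC with 0 left


class TestTune:
    def test_singleton_grid(self):
        fm = gaussian_task(n_pos=5, n_neg=10, seed=7)
        res = tune(fm, KNNMissingClassifier(), "k", [3])
        assert res.best == 3

    def test_tie_resolves_to_smallest(self, separable_fm):
        # fully separable: k=1 and k=3 both reach AUC 1.0
        res = tune(separable_fm, KNNMissingClassifier(), "k", [1, 3, 5])
        assert res.grid[1] == res.grid[3] == 1.0
        assert res.best == 1

    def test_empty_grid_rejected(self):
        fm = gaussian_task(n_pos=5, n_neg=10, seed=8)
        with pytest.raises(ConfigError):
            tune(fm, KNNMissingClassifier(), "k", [])


class TestIndependentTest:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted_models():
        cfg = small_study_config()
        study = generate_study(cfg)
        markers = sorted(study.truth)
        models = {}
        for ds in study.datasets:
            fm = feature_matrix(ds, markers)
            est = BaggingTreesClassifier(n_trees=11, random_state=2).fit(
                fm.values, fm.label_array
            )
            models[ds.dataset_id] = DatasetModel(
                ds.dataset_id, ds.platform.family, markers, est
            )
        return cfg, study, markers, models

    def test_only_matching_family_applied(self, fitted_models):
        cfg, study, markers, models = fitted_models
        ind = generate_independent_set(cfg, study.platforms[CODELINK_LIKE])
        results, skipped = independent_test(models, feature_matrix(ind, markers))
        assert set(results) == {"DMC", "GSE8858"}
        assert set(skipped) == {"DMA", "TG-GATEs"}

    def test_self_test_equals_resubstitution(self, fitted_models):
        cfg, study, markers, models = fitted_models
        ds = study.datasets[1]
        fm = feature_matrix(ds, markers)
        results, _ = independent_test({"DMC": models["DMC"]}, fm)
        resub = models["DMC"].estimator.predict_score(fm.values)
        expected = roc_auc(ScoreSet(fm.chemicals, resub, fm.label_array)).auc
        assert results["DMC"].auc == pytest.approx(expected)

    def test_strong_effect_high_auc(self, fitted_models):
        cfg, study, markers, models = fitted_models
        ind = generate_independent_set(cfg, study.platforms[CODELINK_LIKE])
        results, _ = independent_test(models, feature_matrix(ind, markers))
        assert results["DMC"].auc >= 0.9

    def test_no_compatible_model_warns(self, fitted_models):
        cfg, study, markers, models = fitted_models
        ind = generate_independent_set(cfg, study.platforms[CODELINK_LIKE])
        fm = feature_matrix(ind, markers)
        only_affy = {k: v for k, v in models.items() if v.family == "affy_like"}
        with pytest.warns(UserWarning):
            results, skipped = independent_test(only_affy, fm)
        assert results == {} and set(skipped) == set(only_affy)
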