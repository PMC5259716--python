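"""Six missing-data-tolerant classifiers as sklearn-style estimators.

Every estimator accepts a chemicals × features matrix with NaN cells both
at fit and at prediction time — the property that motivated excluding
margin-based methods from the modelling stage.  All expose
``predict_proba`` (columns ordered by ``classes_``), ``predict`` (hard
call at score 0.5, ties broken toward the negative class — no positive
hazard call without majority evidence), and ``predict_score`` (probability
of the positive class, NGHC by default), and compose with
``sklearn.base.clone`` and pipelines.

Algorithms:

* :class:`C45TreeClassifier` — gain-ratio binary splits, fractional
  routing of missing values, pessimistic pruning.
* :class:`BaggingTreesClassifier` — bootstrap-resampled trees; the score
  is the mean member class-probability (equal to the vote fraction when
  leaves are pure).
* :class:`AdaBoostM1Classifier` — reweighting AdaBoost.M1 over pruned
  trees, early stop at weighted error 0 or ≥ 0.5.
* :class:`RandomForestMissingClassifier` — unpruned trees on bootstrap
  resamples with ``1 + floor(log2 M)`` candidate features per node.
* :class:`GaussianNBMissing` — per-class Gaussian likelihoods; missing
  features drop out of the product.
* :class:`KNNMissingClassifier` — Euclidean distance over mutually
  observed features rescaled by ``sqrt(M / m_observed)``.

Ensemble member ``i`` is seeded from ``(random_state, i)``, so an ensemble
of 10 trees is a prefix of the same-seeded ensemble of 20.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from toxmark import _tree
from toxmark.errors import ConfigError

__all__ = [
    "C45TreeClassifier",
    "BaggingTreesClassifier",
    "AdaBoostM1Classifier",
    "RandomForestMissingClassifier",
    "GaussianNBMissing",
    "KNNMissingClassifier",
    "ALGORITHMS",
    "make_classifier",
    "serialize_model",
    "deserialize_model",
]

_SERIAL_VERSION = 1


def _member_rng(random_state, index: int) -> np.random.Generator:
    seed = 0 if random_state is None else int(random_state)
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, index]))


class _MissingTolerantClassifier(BaseEstimator, ClassifierMixin):
    """Shared input validation and the score→label contract."""

    positive_label = "NGHC"

    def _validate(self, X, y=None, fitting=False):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if fitting:
            y = np.asarray(y)
            if y.shape[0] != X.shape[0]:
                raise ValueError("X and y length mismatch")
            classes = np.unique(y)
            if classes.size > 2:
                raise ValueError("binary classification only")
            if self.positive_label in classes:
                pos = self.positive_label
                neg_candidates = [c for c in classes if c != pos]
                neg = neg_candidates[0] if neg_candidates else f"not_{pos}"
            else:
                pos = classes[-1]
                neg = classes[0]
            # classes_ ordered [negative, positive] so proba[:, 1] is the score
            self.classes_ = np.asarray([neg, pos])
            self.n_features_in_ = X.shape[1]
            y01 = (y == pos).astype(int)
            return X, y01
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fitted with {self.n_features_in_}"
            )
        return X

    def predict_score(self, X) -> np.ndarray:
        """Probability of the positive class (NGHC) per row."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        score = self.predict_score(X)
        # tie at exactly 0.5 -> negative class
        return np.where(score > 0.5, self.classes_[1], self.classes_[0])


class C45TreeClassifier(_MissingTolerantClassifier):
    """C4.5-style decision tree tolerant of missing values.

    Parameters mirror the classical defaults: ``confidence_factor`` 0.25
    for pessimistic pruning and ``min_leaf`` 2 instances per leaf.
    ``max_features`` (used by the random forest) samples a feature subset
    per node; ``prune=False`` grows the tree fully.
    """

    def __init__(
        self,
        confidence_factor: float = 0.25,
        min_leaf: float = 2.0,
        prune: bool = True,
        max_features: int | None = None,
        random_state=None,
    ):
        self.confidence_factor = confidence_factor
        self.min_leaf = min_leaf
        self.prune = prune
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        if not (0 < self.confidence_factor <= 0.5):
            raise ConfigError("confidence_factor must be in (0, 0.5]")
        X, y01 = self._validate(X, y, fitting=True)
        w = (
            np.ones(X.shape[0])
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float)
        )
        rng = _member_rng(self.random_state, 0)
        self.root_ = _tree.grow(
            X, y01, w, min_leaf=self.min_leaf, max_features=self.max_features, rng=rng
        )
        if self.prune:
            _tree.prune(self.root_, self.confidence_factor)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        return np.array([_tree.class_distribution(self.root_, row) for row in X])


class _TreeEnsemble(_MissingTolerantClassifier):
    """Bootstrap ensembles of trees; score = mean member class-probability."""

    def __init__(self, n_trees: int = 10, random_state=None):
        self.n_trees = n_trees
        self.random_state = random_state

    # subclass hooks
    _bootstrap = True
    _prune_members = True
    _member_max_features = staticmethod(lambda m: None)

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ConfigError("n_trees must be at least 1")
        X, y01 = self._validate(X, y, fitting=True)
        n, m = X.shape
        max_features = self._member_max_features(m)
        self.trees_ = []
        for i in range(self.n_trees):
            rng = _member_rng(self.random_state, i)
            idx = rng.integers(0, n, size=n) if self._bootstrap else np.arange(n)
            root = _tree.grow(
                X[idx],
                y01[idx],
                np.ones(n),
                min_leaf=2.0,
                max_features=max_features,
                rng=rng,
            )
            if self._prune_members:
                _tree.prune(root, 0.25)
            self.trees_.append(root)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        proba = np.zeros((X.shape[0], 2))
        for root in self.trees_:
            proba += np.array([_tree.class_distribution(root, row) for row in X])
        return proba / len(self.trees_)


class BaggingTreesClassifier(_TreeEnsemble):
    """Bagged pruned trees; ``bootstrap=False`` (a test hook) makes
    ``n_trees=1`` reduce exactly to :class:`C45TreeClassifier`."""

    def __init__(self, n_trees: int = 10, bootstrap: bool = True, random_state=None):
        super().__init__(n_trees=n_trees, random_state=random_state)
        self.bootstrap = bootstrap

    def fit(self, X, y):
        self._bootstrap = self.bootstrap
        return super().fit(X, y)


class RandomForestMissingClassifier(_TreeEnsemble):
    """Unpruned bootstrap trees with ``1 + floor(log2 M)`` features per node."""

    _prune_members = False

    @staticmethod
    def _member_max_features(m: int) -> int:
        return min(m, 1 + int(math.floor(math.log2(m)))) if m > 0 else 1

    @staticmethod
    def n_candidate_features(m: int) -> int:
        return RandomForestMissingClassifier._member_max_features(m)


class AdaBoostM1Classifier(_MissingTolerantClassifier):
    """AdaBoost.M1 over pruned trees (reweighting form).

    Rounds stop early when a member's weighted error reaches 0 or ≥ 0.5;
    the score is the alpha-weighted fraction of members voting positive.
    """

    def __init__(self, n_trees: int = 10, random_state=None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ConfigError("n_trees must be at least 1")
        X, y01 = self._validate(X, y, fitting=True)
        n = X.shape[0]
        w = np.full(n, 1.0 / n)
        self.trees_ = []
        self.alphas_ = []
        for i in range(self.n_trees):
            root = _tree.grow(X, y01, w * n, min_leaf=2.0)
            _tree.prune(root, 0.25)
            pred = np.array(
                [_tree.class_distribution(root, row)[1] > 0.5 for row in X], dtype=int
            )
            err = float(w[pred != y01].sum())
            if err >= 0.5:
                if not self.trees_:  # first member unusable -> prior-only model
                    self.trees_.append(root)
                    self.alphas_.append(1.0)
                break
            if err == 0.0:
                self.trees_.append(root)
                self.alphas_.append(math.log(1e10))
                break
            beta_m = err / (1.0 - err)
            self.trees_.append(root)
            self.alphas_.append(math.log(1.0 / beta_m))
            w = np.where(pred == y01, w * beta_m, w)
            w /= w.sum()
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        alphas = np.asarray(self.alphas_)
        votes = np.zeros(X.shape[0])
        for root, alpha in zip(self.trees_, alphas):
            member = np.array(
                [_tree.class_distribution(root, row)[1] > 0.5 for row in X], dtype=float
            )
            votes += alpha * member
        score = votes / alphas.sum()
        return np.column_stack([1.0 - score, score])


class GaussianNBMissing(_MissingTolerantClassifier):
    """Gaussian naive Bayes whose likelihood product skips missing features.

    A feature with fewer than two observed values in a class is skipped for
    that class.  Variances are floored at ``var_floor``.  A row with no
    usable feature scores the class prior.
    """

    def __init__(self, var_floor: float = 1e-9):
        self.var_floor = var_floor

    def fit(self, X, y):
        X, y01 = self._validate(X, y, fitting=True)
        n, m = X.shape
        self.priors_ = np.array([(y01 == 0).mean(), (y01 == 1).mean()])
        self.theta_ = np.full((2, m), np.nan)
        self.var_ = np.full((2, m), np.nan)
        for c in (0, 1):
            rows = X[y01 == c]
            for j in range(m):
                col = rows[:, j]
                col = col[~np.isnan(col)]
                if col.size >= 2:
                    self.theta_[c, j] = col.mean()
                    self.var_[c, j] = max(col.var(ddof=0), self.var_floor)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        with np.errstate(divide="ignore"):
            log_prior = np.where(self.priors_ > 0, np.log(self.priors_), -np.inf)
        out = np.empty((X.shape[0], 2))
        for i, row in enumerate(X):
            logp = log_prior.copy()
            for c in (0, 1):
                usable = ~np.isnan(row) & ~np.isnan(self.theta_[c])
                if usable.any():
                    var = self.var_[c, usable]
                    diff = row[usable] - self.theta_[c, usable]
                    logp[c] += float(
                        -0.5 * np.sum(np.log(2 * np.pi * var) + diff**2 / var)
                    )
            shift = logp - logp.max()
            p = np.exp(shift)
            out[i] = p / p.sum()
        return out


class KNNMissingClassifier(_MissingTolerantClassifier):
    """k-nearest neighbours with observed-dimension Euclidean distance.

    Distance between two vectors uses only mutually observed features and
    is rescaled by ``sqrt(M / m_observed)``; a pair with no mutually
    observed feature is infinitely far.  Distance ties break by training
    order.  The score is the NGHC fraction among the k nearest; if every
    training row is unreachable the score falls back to the class prior.
    """

    def __init__(self, k: int = 3):
        self.k = k

    def fit(self, X, y):
        if self.k < 1:
            raise ConfigError("k must be at least 1")
        X, y01 = self._validate(X, y, fitting=True)
        if self.k > X.shape[0]:
            raise ConfigError(f"k={self.k} exceeds {X.shape[0]} training chemicals")
        self.X_ = X
        self.y01_ = y01
        self.prior_ = float(y01.mean())
        return self

    def _distances(self, row: np.ndarray) -> np.ndarray:
        m = self.X_.shape[1]
        diff = self.X_ - row  # NaN wherever either side is missing
        obs = ~np.isnan(diff)
        m_obs = obs.sum(axis=1)
        ss = np.nansum(diff**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt(ss * (m / m_obs))
        d[m_obs == 0] = np.inf
        return d

    def predict_proba(self, X) -> np.ndarray:
        X = self._validate(X)
        out = np.empty((X.shape[0], 2))
        n = self.X_.shape[0]
        for i, row in enumerate(X):
            d = self._distances(row)
            order = np.lexsort((np.arange(n), d))  # ties -> training order
            nearest = order[: self.k]
            if np.isinf(d[nearest]).all():
                score = self.prior_
            else:
                score = float(self.y01_[nearest].mean())
            out[i] = (1.0 - score, score)
        return out


ALGORITHMS = {
    "tree": C45TreeClassifier,
    "bagging": BaggingTreesClassifier,
    "boosting": AdaBoostM1Classifier,
    "random_forest": RandomForestMissingClassifier,
    "naive_bayes": GaussianNBMissing,
    "knn": KNNMissingClassifier,
}


def make_classifier(algorithm: str, **params):
    """Instantiate one of the six classifier families by name."""
    if algorithm not in ALGORITHMS:
        raise ConfigError(f"unknown algorithm {algorithm!r}; choose from {sorted(ALGORITHMS)}")
    return ALGORITHMS[algorithm](**params)


def serialize_model(model) -> dict:
    """Fitted model -> versioned JSON-compatible document."""
    algorithm = next(k for k, cls in ALGORITHMS.items() if type(model) is cls)
    doc = {
        "format_version": _SERIAL_VERSION,
        "algorithm": algorithm,
        "params": model.get_params(),
        "classes": [str(c) for c in model.classes_],
        "n_features_in": int(model.n_features_in_),
    }
    if isinstance(model, C45TreeClassifier):
        doc["tree"] = _tree.node_to_dict(model.root_)
    elif isinstance(model, _TreeEnsemble):
        doc["trees"] = [_tree.node_to_dict(t) for t in model.trees_]
    elif isinstance(model, AdaBoostM1Classifier):
        doc["trees"] = [_tree.node_to_dict(t) for t in model.trees_]
        doc["alphas"] = [float(a) for a in model.alphas_]
    elif isinstance(model, GaussianNBMissing):
        doc["priors"] = model.priors_.tolist()
        doc["theta"] = model.theta_.tolist()
        doc["var"] = model.var_.tolist()
    elif isinstance(model, KNNMissingClassifier):
        doc["X"] = model.X_.tolist()
        doc["y01"] = model.y01_.tolist()
        doc["prior"] = model.prior_
    return doc


def deserialize_model(doc: dict):
    """Inverse of :func:`serialize_model`."""
    if doc.get("format_version") != _SERIAL_VERSION:
        raise ConfigError("unsupported model document version")
    model = make_classifier(doc["algorithm"], **doc["params"])
    model.classes_ = np.asarray(doc["classes"])
    model.n_features_in_ = int(doc["n_features_in"])
    if isinstance(model, C45TreeClassifier):
        model.root_ = _tree.node_from_dict(doc["tree"])
    elif isinstance(model, _TreeEnsemble):
        model.trees_ = [_tree.node_from_dict(t) for t in doc["trees"]]
    elif isinstance(model, AdaBoostM1Classifier):
        model.trees_ = [_tree.node_from_dict(t) for t in doc["trees"]]
        model.alphas_ = [float(a) for a in doc["alphas"]]
    elif isinstance(model, GaussianNBMissing):
        model.priors_ = np.asarray(doc["priors"])
        model.theta_ = np.asarray(doc["theta"])
        model.var_ = np.asarray(doc["var"])
    elif isinstance(model, KNNMissingClassifier):
        model.X_ = np.asarray(doc["X"], dtype=float)
        model.y01_ = np.asarray(doc["y01"], dtype=int)
        model.prior_ = float(doc["prior"])
    return model
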