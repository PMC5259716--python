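"""Score-based evaluation: ROC/AUC, leave-one-out CV, tuning, independent test.

The AUC follows the pairwise (Mann–Whitney) definition — the fraction of
positive–negative pairs where the positive outscores the negative, ties
counted half — which equals the trapezoidal area under the ROC curve when
tied scores are grouped into single threshold steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from toxmark.data import NGHC, FeatureMatrix
from toxmark.errors import ConfigError, InsufficientDataError

__all__ = [
    "ScoreSet",
    "RocResult",
    "roc_auc",
    "loocv",
    "TuningResult",
    "tune",
    "independent_test",
    "DatasetModel",
]


@dataclass
class ScoreSet:
    """Per-chemical classifier scores with true labels."""

    chemicals: list[str]
    scores: np.ndarray
    labels: np.ndarray  # true labels, same order
    flagged: list[str] = field(default_factory=list)  # folds scored by prior only

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.isfinite(self.scores).all():
            raise ConfigError("scores must be finite")


@dataclass
class RocResult:
    """ROC curve (FPR, TPR) points and the area under it."""

    curve: np.ndarray  # (k, 2) array of (FPR, TPR), (0,0) .. (1,1)
    auc: float


def roc_auc(scores: ScoreSet, positive: str = NGHC) -> RocResult:
    """ROC curve and AUC with tied scores grouped into single steps."""
    y = scores.labels == positive
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("AUC undefined: both classes required")
    order = np.argsort(-scores.scores, kind="stable")
    s = scores.scores[order]
    yy = y[order]
    # group tied scores
    boundaries = np.nonzero(np.diff(s))[0]
    ends = np.append(boundaries, s.size - 1)
    tp = np.cumsum(yy)[ends]
    fp = np.cumsum(~yy)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos, [1.0]])
    fpr = np.concatenate([[0.0], fp / n_neg, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    curve = np.column_stack([fpr, tpr])
    return RocResult(curve, auc)


def _fold_seed(master_seed: int, fold: int) -> int:
    return int(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, fold]).generate_state(1)[0]
        % (2**31)
    )


def loocv(
    data: FeatureMatrix,
    estimator,
    master_seed: int = 0,
    positive: str = NGHC,
) -> ScoreSet:
    """Leave-one-out cross-validated scores.

    The i-th held-out score comes from a fresh clone of ``estimator`` never
    trained on chemical i; each fold's clone is seeded from the master seed
    and the fold index (when the estimator takes a ``random_state``).  A
    fold whose training portion collapses to one class is scored by the
    training prior of the positive class and flagged.
    """
    n = len(data.chemicals)
    if n < 3:
        raise ConfigError("leave-one-out needs at least 3 chemicals")
    y = data.label_array
    scores = np.empty(n)
    flagged: list[str] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_train = y[mask]
        if np.unique(y_train).size < 2:
            scores[i] = float((y_train == positive).mean())
            flagged.append(data.chemicals[i])
            continue
        model = clone(estimator)
        if "random_state" in model.get_params():
            model.set_params(random_state=_fold_seed(master_seed, i))
        model.fit(data.values[mask], y_train)
        scores[i] = float(model.predict_score(data.values[i : i + 1])[0])
    return ScoreSet(list(data.chemicals), scores, y, flagged)


@dataclass
class TuningResult:
    """LOOCV AUC per grid point; ties resolve to the smallest parameter."""

    grid: dict
    best: object

    def __post_init__(self):
        best_auc = max(self.grid.values())
        assert self.grid[self.best] == best_auc


def tune(
    data: FeatureMatrix,
    estimator,
    param_name: str,
    grid,
    master_seed: int = 0,
) -> TuningResult:
    """Select ``param_name`` by LOOCV AUC over ``grid`` (non-nested).

    The same LOOCV both selects the parameter and reports its AUC, which
    is optimistically biased; see the methods note.
    """
    grid = list(grid)
    if not grid:
        raise ConfigError("empty tuning grid")
    aucs: dict = {}
    for value in grid:
        model = clone(estimator).set_params(**{param_name: value})
        aucs[value] = roc_auc(loocv(data, model, master_seed)).auc
    best = min((v for v in grid if aucs[v] == max(aucs.values()))) if grid else None
    return TuningResult(aucs, best)


@dataclass
class DatasetModel:
    """A model fitted on one dataset, with its platform family and features."""

    dataset_id: str
    family: str
    features: list[str]
    estimator: object  # fitted


def independent_test(
    models: dict[str, DatasetModel],
    test: FeatureMatrix,
) -> tuple[dict[str, RocResult], list[str]]:
    """Score an independent set with platform-family-matched models only.

    Models whose training platform family differs from the test set's are
    reported as skipped, never scored — cross-family probe universes are
    incomparable without gene-level mapping.  Returns (results, skipped).
    """
    results: dict[str, RocResult] = {}
    skipped: list[str] = []
    for ds_id, dm in models.items():
        if test.family is not None and dm.family != test.family:
            skipped.append(ds_id)
            continue
        aligned = test.restrict(dm.features) if dm.features != test.features else test
        scores = dm.estimator.predict_score(aligned.values)
        results[ds_id] = roc_auc(
            ScoreSet(list(test.chemicals), scores, test.label_array)
        )
    if not results:
        warnings.warn("no platform-compatible model for the independent set")
    return results, skipped
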