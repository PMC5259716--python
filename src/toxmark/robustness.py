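"""Biomarker robustness by overlap-constrained resampling.

Robustness of a marker set is assessed on many random chemical subsets of
one dataset, each preserving the dataset's NGHC/NHC ratio and pairwise
sharing strictly less than half its chemicals with every other subset, so
the subsets are substantially distinct draws rather than reshuffles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from toxmark.data import NGHC, NHC, FeatureMatrix
from toxmark.errors import ConfigError, InfeasiblePlanError, InsufficientDataError
from toxmark.evaluation import loocv, roc_auc

__all__ = [
    "SubsetPlanConfig",
    "SubsetPlan",
    "sample_constrained_subsets",
    "verify_plan",
    "marker_subsets",
    "RobustnessSummary",
    "robustness_auc",
]


@dataclass
class SubsetPlanConfig:
    """Defaults follow the published protocol: 60 subsets of 80 chemicals
    with pairwise overlap strictly below 50%."""

    n_subsets: int = 60
    subset_size: int = 80
    max_overlap_fraction: float = 0.5
    preserve_ratio: bool = True
    max_attempts: int = 100_000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.max_overlap_fraction <= 1):
            raise ConfigError("max_overlap_fraction must be in (0, 1]")
        if self.n_subsets < 1 or self.subset_size < 1:
            raise ConfigError("counts must be positive")


@dataclass
class SubsetPlan:
    subsets: list[tuple[str, ...]]  # sorted chemical ids per subset
    overlap_matrix: np.ndarray

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def _class_targets(n_pos: int, n_neg: int, size: int) -> tuple[int, int]:
    """Nearest-integer per-class targets; the remainder goes to the majority."""
    pool = n_pos + n_neg
    minority, majority = (n_pos, n_neg) if n_pos <= n_neg else (n_neg, n_pos)
    k_minority = int(round(size * minority / pool))
    k_majority = size - k_minority
    if n_pos <= n_neg:
        return k_minority, k_majority
    return k_majority, k_minority


def sample_constrained_subsets(
    chemicals: list[str],
    labels: dict[str, str],
    config: SubsetPlanConfig,
) -> SubsetPlan:
    """Greedy rejection sampling of ratio-preserving, overlap-bounded subsets.

    Phase 1 — rejection sampling: draw a ratio-preserving random subset;
    accept it iff its intersection with every previously accepted subset
    stays strictly below ``max_overlap_fraction × subset_size``; repeat.
    ``max_attempts`` bounds the draws spent on any single subset.

    Phase 2 — when rejection stalls (tight plans such as 60 subsets of 80
    from a 177-chemical pool leave almost no slack: the average pairwise
    overlap of any such plan is ≥ 35.4 against a bound of 40, and blind
    draws stop being accepted around 50 placed subsets), the full plan is
    rebuilt by a balanced construction: element multiplicities are dealt
    as evenly as possible across subsets (preserving per-subset class
    counts), then penalty-guided single-element swaps repair the few pairs
    at or above the bound.  An :class:`InfeasiblePlanError` is raised only
    if the repair cannot finish either.

    Both phases are fully deterministic given the config seed, and every
    returned plan satisfies all invariants (checkable with
    :func:`verify_plan`).
    """
    pool = list(chemicals)
    n_pool = len(pool)
    if config.subset_size > n_pool:
        raise ConfigError("subset_size exceeds pool size")
    pos_idx = np.array([i for i, c in enumerate(pool) if labels[c] == NGHC])
    neg_idx = np.array([i for i, c in enumerate(pool) if labels[c] == NHC])
    if config.preserve_ratio:
        k_pos, k_neg = _class_targets(len(pos_idx), len(neg_idx), config.subset_size)
        if k_pos > len(pos_idx) or k_neg > len(neg_idx):
            raise ConfigError("per-class targets unattainable from this pool")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x5B5]))
    bound = config.max_overlap_fraction * config.subset_size
    class_groups = (
        [(pos_idx, k_pos), (neg_idx, k_neg)]
        if config.preserve_ratio
        else [(np.arange(n_pool), config.subset_size)]
    )
    accepted = _rejection_phase(rng, n_pool, class_groups, bound, config)
    if accepted is None:
        accepted = _balanced_repair_phase(rng, n_pool, class_groups, bound, config)
    overlap = (accepted @ accepted.T).astype(int)
    subsets = [tuple(sorted(pool[i] for i in np.nonzero(row)[0])) for row in accepted]
    return SubsetPlan(subsets, overlap)


def _draw_batch(rng, batch: int, n_pool: int, class_groups) -> np.ndarray:
    """Batch of uniform ratio-preserving subset indicators."""
    cand = np.zeros((batch, n_pool))
    for idx, k in class_groups:
        order = rng.random((batch, len(idx))).argsort(axis=1)[:, :k]
        rows = np.repeat(np.arange(batch), k)
        cand[rows, idx[order].ravel()] = 1.0
    return cand


def _rejection_phase(rng, n_pool, class_groups, bound, config) -> np.ndarray | None:
    """Greedy rejection sampling; None when a subset cannot be placed."""
    batch = 512
    accepted = np.zeros((config.n_subsets, n_pool), dtype=np.float64)
    n_accepted = 0
    attempts = 0  # draws spent on the subset currently being placed
    while n_accepted < config.n_subsets:
        if attempts >= config.max_attempts:
            return None
        cand = _draw_batch(rng, batch, n_pool, class_groups)
        max_ov = (
            (cand @ accepted[:n_accepted].T).max(axis=1)
            if n_accepted
            else np.zeros(batch)
        )
        for r in range(batch):
            if attempts >= config.max_attempts or n_accepted >= config.n_subsets:
                break
            attempts += 1
            ok = max_ov[r] < bound
            # re-check against subsets accepted earlier in this same batch
            if ok and n_accepted and (accepted[:n_accepted] @ cand[r]).max() >= bound:
                ok = False
            if ok:
                accepted[n_accepted] = cand[r]
                n_accepted += 1
                attempts = 0
    return accepted


def _deal_balanced(rng, n_subsets: int, k: int, idx: np.ndarray) -> np.ndarray:
    """0/1 assignment of one class: row sums k, column sums as even as possible."""
    n_elem = len(idx)
    total = n_subsets * k
    base, extra = divmod(total, n_elem)
    mult = np.full(n_elem, base)
    mult[rng.permutation(n_elem)[:extra]] += 1
    capacity = np.full(n_subsets, k)
    a = np.zeros((n_subsets, n_elem))
    for e in np.argsort(-(mult + rng.random(n_elem))):
        rows = np.argsort(-(capacity + rng.random(n_subsets)))[: mult[e]]
        a[rows, e] = 1.0
        capacity[rows] -= 1
    if (capacity != 0).any():  # cannot happen for feasible margins
        raise InfeasiblePlanError("balanced dealing failed", n_placed=0)
    return a


def _balanced_repair_phase(rng, n_pool, class_groups, bound, config) -> np.ndarray:
    """Evenly dealt plan polished by penalty-guided single-element swaps."""
    n_subsets = config.n_subsets
    blocks = [_deal_balanced(rng, n_subsets, k, idx) for idx, k in class_groups]
    a = np.zeros((n_subsets, n_pool))
    cls = np.zeros(n_pool, dtype=int)
    for c, (block, (idx, _)) in enumerate(zip(blocks, class_groups)):
        a[:, idx] = block
        cls[idx] = c
    margin = int(np.ceil(bound)) - 1  # largest admissible integer overlap

    def penalty(x):
        # pairs above the bound cost quadratically; pairs exactly at the
        # margin cost a little, steering repairs toward interior slack
        return np.maximum(0, x - margin) ** 2 + 0.02 * (x == margin)

    max_iter = 200 * n_subsets
    for _ in range(max_iter):
        ov = a @ a.T
        np.fill_diagonal(ov, -1)
        if ov.max() < bound:
            return a
        viol = np.argwhere(ov >= bound)
        i, j = viol[rng.integers(len(viol))]
        shared = np.nonzero((a[i] == 1) & (a[j] == 1))[0]
        best = None
        for e in shared:
            base = ov[i] - a[:, e]
            base[i] = -1
            cost0 = penalty(base).sum()
            gain = penalty(base + 1) - penalty(base)
            cand_f = np.nonzero((a[i] == 0) & (cls == cls[e]))[0]
            if len(cand_f) == 0:
                continue
            pen = cost0 + gain @ a[:, cand_f] + rng.random(len(cand_f)) * 1e-6
            k_best = int(np.argmin(pen))
            if best is None or pen[k_best] < best[0]:
                best = (pen[k_best], e, cand_f[k_best])
        if best is None:
            continue
        _, e, f = best
        a[i, e] = 0.0
        a[i, f] = 1.0
    raise InfeasiblePlanError(
        f"overlap repair did not converge within {max_iter} swaps", n_placed=0
    )


def verify_plan(
    plan: SubsetPlan, labels: dict[str, str], config: SubsetPlanConfig
) -> None:
    """Independent checker of the plan invariants (size, overlap, ratio).

    Recomputes everything from the subsets themselves; raises
    ``AssertionError`` on any violation.
    """
    bound = config.max_overlap_fraction * config.subset_size
    pool_pos = sum(1 for lab in labels.values() if lab == NGHC)
    pool_neg = sum(1 for lab in labels.values() if lab == NHC)
    k_pos, k_neg = _class_targets(pool_pos, pool_neg, config.subset_size)
    for i, subset in enumerate(plan.subsets):
        assert len(subset) == config.subset_size, f"subset {i} has wrong size"
        assert len(set(subset)) == len(subset), f"subset {i} has duplicates"
        if config.preserve_ratio:
            n_pos = sum(1 for c in subset if labels[c] == NGHC)
            assert n_pos == k_pos and len(subset) - n_pos == k_neg, (
                f"subset {i} class composition {n_pos}/{len(subset) - n_pos} "
                f"!= {k_pos}/{k_neg}"
            )
        for j in range(i):
            inter = len(set(subset) & set(plan.subsets[j]))
            assert inter < bound, f"subsets {j},{i} overlap {inter} >= {bound}"
            assert plan.overlap_matrix[i, j] == inter


def marker_subsets(markers: list[str]) -> list[list[str]]:
    """All leave-one-marker-out subsets, in marker order (drop index 0, 1, ...)."""
    if len(markers) < 2:
        raise ConfigError("need at least 2 markers to form leave-one-out subsets")
    return [[m for j, m in enumerate(markers) if j != i] for i in range(len(markers))]


@dataclass
class RobustnessSummary:
    aucs: list[float]
    mean: float
    sd: float
    failed_subsets: list[int] = field(default_factory=list)

    @classmethod
    def from_aucs(cls, aucs: list[float], failed: list[int] | None = None):
        arr = np.asarray(aucs, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(list(aucs), float(arr.mean()), sd, failed or [])


def robustness_auc(
    data: FeatureMatrix,
    markers: list[str],
    plan: SubsetPlan,
    estimator,
    master_seed: int = 0,
) -> RobustnessSummary:
    """Per-subset LOOCV AUC of ``estimator`` on the marker features.

    Subsets where the AUC is undefined (single class after restriction,
    which cannot occur under ratio preservation) are excluded and flagged.
    """
    missing = set().union(*map(set, plan.subsets)) - set(data.chemicals)
    if missing:
        raise ConfigError(f"plan chemicals absent from dataset: {sorted(missing)[:3]}")
    sub_features = data.restrict(markers)
    index = {c: i for i, c in enumerate(data.chemicals)}
    aucs: list[float] = []
    failed: list[int] = []
    for s, subset in enumerate(plan.subsets):
        rows = [index[c] for c in subset]
        sub = FeatureMatrix(
            list(subset),
            list(markers),
            sub_features.values[rows],
            {c: data.labels[c] for c in subset},
            data.family,
        )
        try:
            scores = loocv(sub, estimator, master_seed=master_seed + s)
            aucs.append(roc_auc(scores).auc)
        except InsufficientDataError:
            failed.append(s)
    if not aucs:
        raise InsufficientDataError("no subset yielded a defined AUC")
    return RobustnessSummary.from_aucs(aucs, failed)
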