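"""Decision-tree core: gain-ratio binary splits on numeric features with
fractional routing of missing values and pessimistic error-based pruning.

The tree follows the classical C4.5 recipe for numeric attributes:

* candidate thresholds are midpoints between consecutive distinct observed
  values of a feature;
* information gain is computed on the instances that observe the feature
  and discounted by the observed-weight fraction; the split is chosen by
  maximum gain ratio among candidates with at least average gain;
* instances missing the split feature descend both branches with weights
  proportional to the observed branch weights (fractional instances);
* leaves store weighted class distributions;
* pruning replaces a subtree by a leaf when the leaf's pessimistic error
  estimate (weight × exact binomial upper confidence bound at the
  configured confidence factor) does not exceed the subtree's, plus the
  customary 0.1 tolerance.

Class labels are encoded 0/1; distributions are ``[w_class0, w_class1]``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import betaincinv, xlogy

_LN2 = math.log(2.0)

_EPS = 1e-12
_MAX_DEPTH = 60


class Node:
    __slots__ = ("feature", "threshold", "left", "right", "w_left", "w_right", "dist")

    def __init__(self, dist: np.ndarray):
        self.dist = dist  # class-weight distribution at this node
        self.feature: int | None = None
        self.threshold: float = 0.0
        self.left: "Node | None" = None
        self.right: "Node | None" = None
        self.w_left: float = 0.0
        self.w_right: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def weight(self) -> float:
        return float(self.dist.sum())

    def make_leaf(self) -> None:
        self.feature = None
        self.left = self.right = None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()


def _weighted_entropy(a, b):
    """``w * H(a, b)`` in bits for weight pairs (0 log 0 = 0), elementwise."""
    w = a + b
    return (xlogy(w, w) - xlogy(a, a) - xlogy(b, b)) / _LN2


def _best_split(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    min_leaf: float,
    feature_idx: np.ndarray,
):
    """Best (feature, threshold) by gain ratio among above-average-gain splits."""
    w_all = w.sum()
    feats: list[np.ndarray] = []
    thrs: list[np.ndarray] = []
    gains: list[np.ndarray] = []
    ratios: list[np.ndarray] = []
    for f in feature_idx:
        col = X[:, f]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            continue
        v = col[obs]
        wv = w[obs]
        yv = y[obs]
        order = np.argsort(v, kind="stable")
        v = v[order]
        wv = wv[order]
        yv = yv[order]
        w1 = wv * yv
        w0 = wv - w1
        c0 = np.cumsum(w0)
        c1 = np.cumsum(w1)
        t0, t1 = c0[-1], c1[-1]
        w_obs = t0 + t1
        cut = np.nonzero(v[1:] > v[:-1])[0]  # split between positions i and i+1
        if cut.size == 0:
            continue
        l0, l1 = c0[cut], c1[cut]
        r0, r1 = t0 - l0, t1 - l1
        wl, wr = l0 + l1, r0 + r1
        valid = (wl >= min_leaf - _EPS) & (wr >= min_leaf - _EPS)
        if not valid.any():
            continue
        wh_parent = _weighted_entropy(t0, t1)
        gain_obs = (wh_parent - _weighted_entropy(l0, l1) - _weighted_entropy(r0, r1)) / w_obs
        gain = (w_obs / w_all) * gain_obs
        w_miss = w_all - w_obs
        # split info over the left / right / missing partition of all weight
        si = (
            xlogy(w_all, w_all) - xlogy(wl, wl) - xlogy(wr, wr) - xlogy(w_miss, w_miss)
        ) / (w_all * _LN2)
        keep = valid & (gain > _EPS) & (si > _EPS)
        if not keep.any():
            continue
        thr = 0.5 * (v[cut] + v[cut + 1])
        feats.append(np.full(keep.sum(), f))
        thrs.append(thr[keep])
        gains.append(gain[keep])
        ratios.append((gain / np.where(si > 0, si, 1.0))[keep])
    if not feats:
        return None
    feat = np.concatenate(feats)
    thr = np.concatenate(thrs)
    gain = np.concatenate(gains)
    ratio = np.concatenate(ratios)
    eligible = gain >= gain.mean() - _EPS
    idx = np.nonzero(eligible)[0]
    best = idx[np.argmax(ratio[idx])]  # first max: lowest feature index, then threshold
    return int(feat[best]), float(thr[best])


def grow(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    min_leaf: float = 2.0,
    max_features: int | None = None,
    rng: np.random.Generator | None = None,
    depth: int = 0,
) -> Node:
    dist = np.array([w[y == 0].sum(), w[y == 1].sum()])
    node = Node(dist)
    total = dist.sum()
    if dist.min() <= _EPS or total < 2 * min_leaf or depth >= _MAX_DEPTH:
        return node
    m = X.shape[1]
    if max_features is not None and max_features < m:
        assert rng is not None
        feature_idx = np.sort(rng.choice(m, size=max_features, replace=False))
    else:
        feature_idx = np.arange(m)
    best = _best_split(X, y, w, min_leaf, feature_idx)
    if best is None:
        return node
    f, thr = best
    col = X[:, f]
    obs = ~np.isnan(col)
    left = obs & (col <= thr)
    right = obs & ~left
    miss = ~obs
    w_left = w[left].sum()
    w_right = w[right].sum()
    w_obs = w_left + w_right
    if w_left < min_leaf - _EPS or w_right < min_leaf - _EPS:
        return node

    def _branch(mask, frac):
        Xb = np.concatenate([X[mask], X[miss]])
        yb = np.concatenate([y[mask], y[miss]])
        wb = np.concatenate([w[mask], w[miss] * frac])
        keep = wb > _EPS
        return Xb[keep], yb[keep], wb[keep]

    node.feature = f
    node.threshold = thr
    node.w_left = w_left
    node.w_right = w_right
    node.left = grow(*_branch(left, w_left / w_obs), min_leaf, max_features, rng, depth + 1)
    node.right = grow(*_branch(right, w_right / w_obs), min_leaf, max_features, rng, depth + 1)
    return node


def _pessimistic_errors(node: Node, cf: float) -> float:
    n = node.weight
    if n <= 0:
        return 0.0
    e = n - node.dist.max()
    if e >= n:
        return n
    # exact binomial upper confidence bound (inverse regularized beta)
    return float(n * betaincinv(e + 1.0, max(n - e, _EPS), 1.0 - cf))


def prune(node: Node, cf: float = 0.25) -> float:
    """Bottom-up pessimistic pruning; returns the subtree's error estimate."""
    if node.is_leaf:
        return _pessimistic_errors(node, cf)
    sub = prune(node.left, cf) + prune(node.right, cf)
    as_leaf = _pessimistic_errors(node, cf)
    if as_leaf <= sub + 0.1:
        node.make_leaf()
        return as_leaf
    return sub


def class_distribution(node: Node, x: np.ndarray) -> np.ndarray:
    """Normalized class distribution for one sample; missing split features
    mix both subtrees weighted by their training branch weights."""
    if node.is_leaf:
        total = node.dist.sum()
        if total <= 0:
            return np.array([0.5, 0.5])
        return node.dist / total
    value = x[node.feature]
    if np.isnan(value):
        s = node.w_left + node.w_right
        return (
            node.w_left * class_distribution(node.left, x)
            + node.w_right * class_distribution(node.right, x)
        ) / s
    child = node.left if value <= node.threshold else node.right
    return class_distribution(child, x)


def node_to_dict(node: Node) -> dict:
    d = {"dist": [float(v) for v in node.dist]}
    if not node.is_leaf:
        d.update(
            feature=int(node.feature),
            threshold=float(node.threshold),
            w_left=float(node.w_left),
            w_right=float(node.w_right),
            left=node_to_dict(node.left),
            right=node_to_dict(node.right),
        )
    return d


def node_from_dict(d: dict) -> Node:
    node = Node(np.asarray(d["dist"], dtype=float))
    if "feature" in d:
        node.feature = int(d["feature"])
        node.threshold = float(d["threshold"])
        node.w_left = float(d["w_left"])
        node.w_right = float(d["w_right"])
        node.left = node_from_dict(d["left"])
        node.right = node_from_dict(d["right"])
    return node
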