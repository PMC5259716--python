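"""Per-dataset differential expression and cross-dataset consensus markers.

A probe is differentially expressed between NGHC- and NHC-treated profiles
when a two-sample t-test gives p < 0.05 (strict) and the fold change on the
original scale is at least 1.5-fold in either direction (inclusive).  A
gene is a DEG if any of its probes passes; the consensus biomarker set is
the intersection of the per-dataset gene-level DEG sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from toxmark.data import NGHC, NHC, ExpressionDataset
from toxmark.errors import ConfigError, InsufficientDataError

__all__ = [
    "DegThresholds",
    "TTestResult",
    "two_group_ttest",
    "gene_fold_change",
    "identify_degs",
    "DegResult",
    "consensus_intersection",
    "ConsensusSet",
]

_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DegThresholds:
    """Significance and fold-change cutoffs for calling a DEG."""

    p_max: float = 0.05
    fc_min: float = 1.5

    def __post_init__(self):
        if not (0 < self.p_max < 1):
            raise ConfigError("p_max must be in (0, 1)")
        if self.fc_min <= 1:
            raise ConfigError("fc_min must exceed 1")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    valid: bool  # False when either group had <2 usable values


def two_group_ttest(x, y, variant: str = "pooled") -> TTestResult:
    """Two-sided two-sample t-test; sign(t) = sign(mean(x) − mean(y)).

    ``variant`` selects classical pooled-variance ("pooled") or Welch
    ("welch") degrees of freedom.  Missing (NaN) values are dropped.  With
    <2 usable values in either group the result is flagged invalid.  Zero
    variance in both groups yields t=0, p=1 at equal means, and the
    smallest positive p at unequal means.
    """
    if variant not in ("pooled", "welch"):
        raise ConfigError(f"unknown t-test variant {variant!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return TTestResult(math.nan, math.nan, False)
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return TTestResult(0.0, 1.0, True)
        return TTestResult(math.copysign(math.inf, diff), _TINY_P, True)
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.pvalue), True)


def gene_fold_change(x_log2, y_log2, convention: str = "geometric") -> tuple[float, float]:
    """Fold change of group A over group B from log2-scale values.

    geometric: ``log2_fc = mean(x_log2) − mean(y_log2)``, ``fc = 2**log2_fc``
    (the ratio of geometric means on the original scale).  arithmetic:
    ``fc = mean(2**x)/mean(2**y)``.  Returns ``(log2_fc, fc)``.
    """
    if convention not in ("geometric", "arithmetic"):
        raise ConfigError(f"unknown fold-change convention {convention!r}")
    x = np.asarray(x_log2, dtype=float)
    y = np.asarray(y_log2, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 1 or y.size < 1:
        raise InsufficientDataError("fold change needs at least one value per group")
    if convention == "geometric":
        log2_fc = float(x.mean() - y.mean())
        return log2_fc, float(2.0**log2_fc)
    fc = float(np.mean(np.exp2(x)) / np.mean(np.exp2(y)))
    return float(np.log2(fc)), fc


@dataclass
class DegResult:
    """Probe-level statistics plus the gene-level DEG call for one dataset."""

    dataset_id: str
    table: pd.DataFrame  # probe, gene, t, p, log2_fc, fc, passes
    gene_degs: set[str]
    thresholds: DegThresholds

    @property
    def probe_degs(self) -> set[str]:
        return set(self.table.loc[self.table["passes"], "probe"])


def _passes(p: np.ndarray, fc: np.ndarray, thr: DegThresholds) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (p < thr.p_max) & ((fc >= thr.fc_min) | (fc <= 1.0 / thr.fc_min))


def identify_degs(
    dataset: ExpressionDataset,
    thresholds: DegThresholds = DegThresholds(),
    variant: str = "pooled",
    convention: str = "geometric",
) -> DegResult:
    """Per-probe NGHC-vs-NHC test and fold change, collapsed to gene DEGs.

    Vectorized over probes; missing cells are dropped per probe per group.
    Probes with <2 usable values in a group cannot pass.  Raises on a
    single-class dataset.
    """
    labels = dataset.label_array
    a = dataset.values[labels == NGHC]  # group A: NGHC-treated
    b = dataset.values[labels == NHC]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise InsufficientDataError(
            f"dataset {dataset.dataset_id}: both NGHC and NHC chemicals required"
        )

    na = (~np.isnan(a)).sum(axis=0).astype(float)
    nb = (~np.isnan(b)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(a, axis=0)
        mean_b = np.nanmean(b, axis=0)
        var_a = np.nanvar(a, axis=0, ddof=1)
        var_b = np.nanvar(b, axis=0, ddof=1)
        diff = mean_a - mean_b
        if variant == "pooled":
            df = na + nb - 2
            pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
            se = np.sqrt(pooled * (1 / na + 1 / nb))
        elif variant == "welch":
            se2a = var_a / na
            se2b = var_b / nb
            se = np.sqrt(se2a + se2b)
            df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
        else:
            raise ConfigError(f"unknown t-test variant {variant!r}")
        t = diff / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    # degenerate probes: zero variance in both groups
    both_const = (var_a == 0) & (var_b == 0)
    t = np.where(both_const & (diff == 0), 0.0, t)
    p = np.where(both_const & (diff == 0), 1.0, p)
    t = np.where(both_const & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    p = np.where(both_const & (diff != 0), _TINY_P, p)
    # insufficient data: cannot pass
    usable = (na >= 2) & (nb >= 2)
    t = np.where(usable, t, np.nan)
    p = np.where(usable, p, np.nan)

    if convention == "geometric":
        log2_fc = diff
        fc = np.exp2(log2_fc)
    elif convention == "arithmetic":
        with np.errstate(invalid="ignore"):
            fc = np.nanmean(np.exp2(a), axis=0) / np.nanmean(np.exp2(b), axis=0)
            log2_fc = np.log2(fc)
    else:
        raise ConfigError(f"unknown fold-change convention {convention!r}")
    fc_usable = (na >= 1) & (nb >= 1)
    fc = np.where(fc_usable, fc, np.nan)
    log2_fc = np.where(fc_usable, log2_fc, np.nan)

    passes = _passes(p, fc, thresholds) & usable

    probes = dataset.platform.probe_ids
    genes = [dataset.platform.probe_to_gene.get(pr, "") for pr in probes]
    table = pd.DataFrame(
        {
            "probe": probes,
            "gene": genes,
            "t": t,
            "p": p,
            "log2_fc": log2_fc,
            "fc": fc,
            "passes": passes,
        }
    )
    gene_degs = set(table.loc[passes & (table["gene"] != ""), "gene"])
    return DegResult(dataset.dataset_id, table, gene_degs, thresholds)


@dataclass
class ConsensusSet:
    """Cross-dataset intersection of gene-level DEG sets, with provenance."""

    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def venn_counts(self) -> dict[str, int]:
        """Number of datasets supporting each gene in any provenance set."""
        support: dict[str, int] = {}
        for geneset in self.provenance.values():
            for g in geneset:
                support[g] = support.get(g, 0) + 1
        sizes: dict[str, int] = {}
        for g, k in support.items():
            key = f"in_{k}_datasets"
            sizes[key] = sizes.get(key, 0) + 1
        return sizes


def consensus_intersection(
    deg_sets: list[set[str]], dataset_ids: list[str] | None = None
) -> ConsensusSet:
    """Exact intersection of ≥2 per-dataset gene-level DEG sets."""
    if not deg_sets:
        raise ConfigError("no DEG sets supplied")
    if len(deg_sets) < 2:
        raise ConfigError("consensus needs at least two DEG sets")
    if dataset_ids is None:
        dataset_ids = [f"set_{i}" for i in range(len(deg_sets))]
    if len(dataset_ids) != len(deg_sets):
        raise ConfigError("dataset_ids length mismatch")
    genes = set.intersection(*(set(s) for s in deg_sets))
    return ConsensusSet(genes, dict(zip(dataset_ids, (set(s) for s in deg_sets))))
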