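"""Shared fixtures: small generated studies and hand-built feature matrices."""

from __future__ import annotations

import numpy as np
import pytest

from toxmark.data import FeatureMatrix
from toxmark.simulate import (
    AFFY_LIKE,
    CODELINK_LIKE,
    DatasetConfig,
    StudyConfig,
    generate_study,
)


def small_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """A reduced-scale four-dataset study for fast unit tests."""
    params = dict(
        datasets=[
            DatasetConfig("DMA", AFFY_LIKE, 8, 15),
            DatasetConfig("DMC", CODELINK_LIKE, 10, 24),
            DatasetConfig("GSE8858", CODELINK_LIKE, 9, 20),
            DatasetConfig("TG-GATEs", AFFY_LIKE, 5, 14),
        ],
        n_genes=40,
        n_planted_markers=3,
        effect_size=-1.0,
        noise_sd=0.4,
        missing_rate=0.05,
        pool_nghc=15,
        pool_nhc=40,
        seed=seed,
    )
    params.update(overrides)
    return StudyConfig(**params)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(small_study_config())


def gaussian_task(
    n_pos: int = 40,
    n_neg: int = 160,
    n_features: int = 4,
    shift: float = -1.0,
    sd: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> FeatureMatrix:
    """Two Gaussian classes on log2-like scale; NGHC shifted by ``shift``.

    The per-feature baseline is a fixed property of the task (its own rng),
    so different ``seed`` values redraw samples from the same population —
    train/test pairs and seed-replicate studies stay distributionally
    matched.
    """
    rng = np.random.default_rng(seed)
    base = np.random.default_rng(986).normal(8.0, 1.0, size=n_features)
    x_pos = base + shift + rng.normal(0, sd, size=(n_pos, n_features))
    x_neg = base + rng.normal(0, sd, size=(n_neg, n_features))
    values = np.vstack([x_pos, x_neg])
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        values[mask] = np.nan
        # keep at least one observed feature per row
        for i in np.nonzero(np.isnan(values).all(axis=1))[0]:
            values[i, 0] = base[0]
    chems = [f"p{i}" for i in range(n_pos)] + [f"n{i}" for i in range(n_neg)]
    labels = {c: ("NGHC" if c.startswith("p") else "NHC") for c in chems}
    return FeatureMatrix(chems, [f"g{j}" for j in range(n_features)], values, labels)


@pytest.fixture
def separable_fm() -> FeatureMatrix:
    """Perfectly separable single-feature task (NGHC low, NHC high).

    Large enough that bootstrap resamples essentially always contain both
    classes, so bagged trees stay pure.
    """
    rng = np.random.default_rng(123)
    low = rng.uniform(1.0, 2.5, size=10)
    high = rng.uniform(7.5, 9.5, size=16)
    values = np.concatenate([low, high])[:, None]
    chems = [f"c{i}" for i in range(26)]
    labels = {c: ("NGHC" if i < 10 else "NHC") for i, c in enumerate(chems)}
    return FeatureMatrix(chems, ["g0"], values, labels)
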