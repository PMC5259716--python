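"""In-memory containers for expression studies and their TSV bundle format.

An :class:`ExpressionDataset` is one platform's chemicals × probes matrix of
log2 expression values (NaN = missing measurement), with per-chemical
NGHC/NHC labels and a probe→gene-symbol annotation.  Gene symbols are the
namespace shared across platforms; probe identifiers are platform-specific.

The on-disk bundle is three TSV files per dataset:

* ``<id>.matrix.tsv``   — rows = chemicals, columns = probes, empty cell = missing
* ``<id>.metadata.tsv`` — columns chemical, label[, dose]
* ``<id>.annotation.tsv`` — columns probe, gene (unmapped probes omitted)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from toxmark.errors import ConfigError

__all__ = [
    "PlatformSpec",
    "ExpressionDataset",
    "FeatureMatrix",
    "feature_matrix",
    "write_dataset_bundle",
    "read_dataset_bundle",
]

NGHC = "NGHC"
NHC = "NHC"


@dataclass
class PlatformSpec:
    """A microarray platform: its probe universe and probe→gene mapping."""

    platform_id: str
    family: str
    probe_ids: list[str]
    probe_to_gene: dict[str, str]

    def __post_init__(self):
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ConfigError(f"platform {self.platform_id}: duplicate probe ids")
        unknown = set(self.probe_to_gene) - set(self.probe_ids)
        if unknown:
            raise ConfigError(
                f"platform {self.platform_id}: annotation references unknown probes"
            )

    @property
    def genes(self) -> set[str]:
        return set(self.probe_to_gene.values())


@dataclass
class ExpressionDataset:
    """One dataset's chemicals × probes log2 expression matrix."""

    dataset_id: str
    platform: PlatformSpec
    chemicals: list[str]
    labels: dict[str, str]
    values: np.ndarray  # (n_chemicals, n_probes), NaN = missing
    doses: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.chemicals) or p != len(self.platform.probe_ids):
            raise ConfigError(
                f"dataset {self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.chemicals)} chemicals × {len(self.platform.probe_ids)} probes"
            )
        missing_labels = [c for c in self.chemicals if c not in self.labels]
        if missing_labels:
            raise ConfigError(
                f"dataset {self.dataset_id}: unlabelled chemicals {missing_labels[:3]}"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and not np.isfinite(present).all():
            raise ConfigError(f"dataset {self.dataset_id}: non-finite expression values")

    @property
    def label_array(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.chemicals])

    def class_counts(self) -> dict[str, int]:
        labels = self.label_array
        return {NGHC: int((labels == NGHC).sum()), NHC: int((labels == NHC).sum())}


@dataclass
class FeatureMatrix:
    """Chemicals × gene-features matrix used for model fitting and scoring."""

    chemicals: list[str]
    features: list[str]
    values: np.ndarray  # (n_chemicals, n_features), NaN = missing
    labels: dict[str, str]
    family: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.features:
            raise ConfigError("feature matrix needs at least one feature")
        if self.values.shape != (len(self.chemicals), len(self.features)):
            raise ConfigError("feature matrix shape mismatch")

    @property
    def label_array(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.chemicals])

    def restrict(self, features: list[str]) -> "FeatureMatrix":
        """Project onto a feature subset (all must be present)."""
        idx = [self.features.index(f) for f in features]
        return FeatureMatrix(
            list(self.chemicals), list(features), self.values[:, idx], dict(self.labels), self.family
        )


def feature_matrix(dataset: ExpressionDataset, genes: list[str]) -> FeatureMatrix:
    """Collapse probe-level expression to gene-level features.

    A gene's feature value for a chemical is the mean of its probes'
    non-missing values (platforms differ in probe redundancy); NaN when no
    probe of the gene was measured.  Genes absent from the platform yield an
    all-NaN column, which keeps feature spaces aligned across platforms.
    """
    probe_idx: dict[str, list[int]] = {g: [] for g in genes}
    for j, probe in enumerate(dataset.platform.probe_ids):
        gene = dataset.platform.probe_to_gene.get(probe)
        if gene in probe_idx:
            probe_idx[gene].append(j)
    n = len(dataset.chemicals)
    out = np.full((n, len(genes)), np.nan)
    for k, gene in enumerate(genes):
        cols = probe_idx[gene]
        if cols:
            with warnings.catch_warnings():
                # chemicals with no observed probe for this gene stay NaN
                warnings.simplefilter("ignore", RuntimeWarning)
                out[:, k] = np.nanmean(dataset.values[:, cols], axis=1)
    return FeatureMatrix(
        list(dataset.chemicals), list(genes), out, dict(dataset.labels), dataset.platform.family
    )


def write_dataset_bundle(dataset: ExpressionDataset, outdir) -> dict[str, Path]:
    """Write one dataset as the three-file TSV bundle; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = dataset.dataset_id
    matrix_path = outdir / f"{ds}.matrix.tsv"
    meta_path = outdir / f"{ds}.metadata.tsv"
    ann_path = outdir / f"{ds}.annotation.tsv"

    mat = pd.DataFrame(dataset.values, index=dataset.chemicals, columns=dataset.platform.probe_ids)
    mat.to_csv(matrix_path, sep="\t", index_label="chemical", na_rep="")

    meta = pd.DataFrame(
        {
            "chemical": dataset.chemicals,
            "label": [dataset.labels[c] for c in dataset.chemicals],
            "dose": [dataset.doses.get(c, "") for c in dataset.chemicals],
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)

    ann = pd.DataFrame(
        sorted(dataset.platform.probe_to_gene.items()), columns=["probe", "gene"]
    )
    ann.to_csv(ann_path, sep="\t", index=False)
    return {"matrix": matrix_path, "metadata": meta_path, "annotation": ann_path}


def read_dataset_bundle(outdir, dataset_id: str, family: str = "unknown") -> ExpressionDataset:
    """Read a dataset bundle written by :func:`write_dataset_bundle`."""
    outdir = Path(outdir)
    mat = pd.read_csv(outdir / f"{dataset_id}.matrix.tsv", sep="\t", index_col="chemical")
    meta = pd.read_csv(outdir / f"{dataset_id}.metadata.tsv", sep="\t")
    ann = pd.read_csv(outdir / f"{dataset_id}.annotation.tsv", sep="\t")
    platform = PlatformSpec(
        platform_id=f"{dataset_id}-platform",
        family=family,
        probe_ids=list(mat.columns),
        probe_to_gene=dict(zip(ann["probe"], ann["gene"])),
    )
    labels = dict(zip(meta["chemical"], meta["label"]))
    doses = {
        c: float(d)
        for c, d in zip(meta["chemical"], meta["dose"])
        if pd.notna(d) and d != ""
    }
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform=platform,
        chemicals=list(mat.index),
        labels=labels,
        values=mat.to_numpy(dtype=float),
        doses=doses,
    )
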