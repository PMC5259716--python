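"""Synthetic multi-dataset expression studies with planted marker genes.

The generator emulates the structure of the real study designs: several
datasets on two platform families with different probe universes, each
profiling its own subset of a shared chemical list at one dose (one log2
profile per chemical), class-imbalanced NGHC/NHC labels, a small set of
genes down-regulated in NGHC-treated profiles, log-normal measurement
noise (Gaussian on the log2 scale), per-platform baseline shifts, and
scattered missing-completely-at-random cells.

Every draw derives from a single master seed through named substreams, so
datasets, the independent test set and downstream resampling stages are
independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from toxmark.data import NGHC, NHC, ExpressionDataset, PlatformSpec
from toxmark.errors import ConfigError

__all__ = [
    "DatasetConfig",
    "StudyConfig",
    "GeneratedStudy",
    "generate_study",
    "generate_independent_set",
    "default_dataset_configs",
]

AFFY_LIKE = "affy_like"  # larger probe universe, 1-3 probes per gene
CODELINK_LIKE = "codelink_like"  # smaller probe universe, 1 probe per gene


@dataclass
class DatasetConfig:
    dataset_id: str
    family: str
    n_nghc: int
    n_nhc: int


def default_dataset_configs() -> list[DatasetConfig]:
    """Four datasets mirroring the real studies' class counts and platforms."""
    return [
        DatasetConfig("DMA", AFFY_LIKE, 25, 47),
        DatasetConfig("DMC", CODELINK_LIKE, 39, 138),
        DatasetConfig("GSE8858", CODELINK_LIKE, 35, 121),
        DatasetConfig("TG-GATEs", AFFY_LIKE, 12, 93),
    ]


@dataclass
class StudyConfig:
    """Parameters of a generated study.

    ``effect_size`` is the log2-units shift applied to planted-marker genes
    in NGHC-treated profiles (negative = down-regulated, as observed for
    the real consensus biomarkers).  ``noise_sd`` is per-cell Gaussian noise
    on the log2 scale.  ``baseline_shift_sd`` scales per-platform per-gene
    baseline offsets.  Pool sizes default to the curated list (50 NGHC,
    224 NHC); per-dataset class counts default to the real datasets.
    """

    datasets: list[DatasetConfig] = field(default_factory=default_dataset_configs)
    n_genes: int = 500
    n_planted_markers: int = 4
    effect_size: float = -1.0
    noise_sd: float = 0.5
    baseline_shift_sd: float = 0.3
    missing_rate: float = 0.05
    pool_nghc: int = 50
    pool_nhc: int = 224
    seed: int = 0

    def validate(self) -> None:
        if self.n_planted_markers > self.n_genes:
            raise ConfigError("n_planted_markers exceeds n_genes")
        if self.n_genes <= 0 or self.n_planted_markers < 0:
            raise ConfigError("gene counts must be positive")
        if not (0 <= self.missing_rate < 1):
            raise ConfigError("missing_rate must be in [0, 1)")
        if self.noise_sd < 0 or self.baseline_shift_sd < 0:
            raise ConfigError("noise scales must be non-negative")
        if not self.datasets:
            raise ConfigError("at least one dataset required")
        for ds in self.datasets:
            if ds.n_nghc <= 0 or ds.n_nhc <= 0:
                raise ConfigError(f"dataset {ds.dataset_id}: class counts must be positive")
            if ds.family not in (AFFY_LIKE, CODELINK_LIKE):
                raise ConfigError(f"dataset {ds.dataset_id}: unknown platform family")
        if max((d.n_nghc for d in self.datasets), default=0) > self.pool_nghc:
            raise ConfigError("NGHC pool smaller than a dataset's NGHC count")
        if max((d.n_nhc for d in self.datasets), default=0) > self.pool_nhc:
            raise ConfigError("NHC pool smaller than a dataset's NHC count")


@dataclass
class GeneratedStudy:
    datasets: list[ExpressionDataset]
    truth: set[str]  # planted marker gene symbols
    chemical_labels: dict[str, str]
    platforms: dict[str, PlatformSpec]
    genes: list[str]


def _rng(seed: int, name: str, *extra: int) -> np.random.Generator:
    """Named substream of the master seed (stable across runs/platforms)."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode()), *extra])
    )


def _study_params(config: StudyConfig):
    """Gene symbols, truth set, platforms and baseline means shared by all sets."""
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    truth_rng = _rng(config.seed, "truth")
    marker_idx = np.sort(
        truth_rng.choice(config.n_genes, size=config.n_planted_markers, replace=False)
    )
    truth = {genes[i] for i in marker_idx}

    plat_rng = _rng(config.seed, "platforms")
    # affy-like family: 1-3 probes per gene plus a few unmapped probes
    affy_probes: list[str] = []
    affy_map: dict[str, str] = {}
    n_probes_per_gene = plat_rng.integers(1, 4, size=config.n_genes)
    for gene, k in zip(genes, n_probes_per_gene):
        for j in range(k):
            pid = f"AF:{gene}:{j}"
            affy_probes.append(pid)
            affy_map[pid] = gene
    for j in range(max(2, config.n_genes // 50)):
        affy_probes.append(f"AF:unmapped:{j}")
    # codelink-like family: exactly 1 probe per gene
    cl_probes = [f"CL:{gene}" for gene in genes]
    cl_map = {f"CL:{gene}": gene for gene in genes}
    platforms = {
        AFFY_LIKE: PlatformSpec("affy_like_array", AFFY_LIKE, affy_probes, affy_map),
        CODELINK_LIKE: PlatformSpec("codelink_like_array", CODELINK_LIKE, cl_probes, cl_map),
    }

    base_rng = _rng(config.seed, "baseline")
    gene_mu = base_rng.normal(8.0, 1.5, size=config.n_genes)
    gene_mu_map = dict(zip(genes, gene_mu))
    # platform baseline offsets per (family, gene); unmapped probes get own baselines
    offsets = {
        fam: dict(
            zip(genes, _rng(config.seed, "platform_shift", zlib.crc32(fam.encode()))
                .normal(0.0, config.baseline_shift_sd, size=config.n_genes))
        )
        for fam in platforms
    }
    probe_base = {}
    for fam, spec in platforms.items():
        unmapped_rng = _rng(config.seed, "unmapped", zlib.crc32(fam.encode()))
        base = np.empty(len(spec.probe_ids))
        for j, pid in enumerate(spec.probe_ids):
            gene = spec.probe_to_gene.get(pid)
            if gene is None:
                base[j] = unmapped_rng.normal(8.0, 1.5)
            else:
                base[j] = gene_mu_map[gene] + offsets[fam][gene]
        probe_base[fam] = base
    return genes, truth, platforms, probe_base


def _chemical_pool(config: StudyConfig) -> tuple[list[str], list[str], dict[str, str]]:
    nghc = [f"nghc_{i:03d}" for i in range(config.pool_nghc)]
    nhc = [f"nhc_{i:03d}" for i in range(config.pool_nhc)]
    labels = {c: NGHC for c in nghc}
    labels.update({c: NHC for c in nhc})
    return nghc, nhc, labels


def _simulate_matrix(
    config: StudyConfig,
    platform: PlatformSpec,
    probe_base: np.ndarray,
    truth: set[str],
    chem_labels: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    n = len(chem_labels)
    p = len(platform.probe_ids)
    values = np.tile(probe_base, (n, 1))
    is_marker_probe = np.array(
        [platform.probe_to_gene.get(pid) in truth for pid in platform.probe_ids]
    )
    is_nghc = np.array([lab == NGHC for lab in chem_labels])
    values[np.ix_(is_nghc, is_marker_probe)] += config.effect_size
    if config.noise_sd > 0:
        values += rng.normal(0.0, config.noise_sd, size=(n, p))
    else:
        rng.normal(0.0, 1.0, size=(n, p))  # keep stream position stable
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        values[mask] = np.nan
    else:
        rng.random((n, p))
    return values


def generate_study(config: StudyConfig) -> GeneratedStudy:
    """Generate all configured datasets; byte-identical for identical seeds."""
    config.validate()
    genes, truth, platforms, probe_base = _study_params(config)
    nghc_pool, nhc_pool, pool_labels = _chemical_pool(config)

    datasets = []
    for ds_cfg in config.datasets:
        pick_rng = _rng(config.seed, "chemicals", zlib.crc32(ds_cfg.dataset_id.encode()))
        chems = sorted(pick_rng.choice(nghc_pool, size=ds_cfg.n_nghc, replace=False)) + sorted(
            pick_rng.choice(nhc_pool, size=ds_cfg.n_nhc, replace=False)
        )
        noise_rng = _rng(config.seed, "expression", zlib.crc32(ds_cfg.dataset_id.encode()))
        platform = platforms[ds_cfg.family]
        values = _simulate_matrix(
            config,
            platform,
            probe_base[ds_cfg.family],
            truth,
            [pool_labels[c] for c in chems],
            noise_rng,
        )
        datasets.append(
            ExpressionDataset(
                dataset_id=ds_cfg.dataset_id,
                platform=platform,
                chemicals=chems,
                labels={c: pool_labels[c] for c in chems},
                values=values,
            )
        )
    return GeneratedStudy(datasets, truth, pool_labels, platforms, genes)


def generate_independent_set(
    config: StudyConfig,
    platform: PlatformSpec,
    n_nghc: int = 9,
    n_nhc: int = 54,
    dataset_id: str = "independent",
) -> ExpressionDataset:
    """Generate an independent test set on an existing platform.

    New chemicals (disjoint from the study pool), same generative model and
    same planted truth genes as :func:`generate_study` under the same
    config.  Defaults mirror the external validation cohort (9 NGHC / 54
    NHC on the small platform family).
    """
    config.validate()
    if n_nghc + n_nhc <= 0:
        raise ConfigError("independent set must contain at least one chemical")
    if n_nghc < 0 or n_nhc < 0:
        raise ConfigError("class counts must be non-negative")
    _, truth, platforms, probe_base = _study_params(config)
    if platform.family not in platforms or platforms[platform.family].platform_id != platform.platform_id:
        raise ConfigError(
            f"platform {platform.platform_id!r} is not one of this study's platforms"
        )
    chems = [f"ind_nghc_{i:03d}" for i in range(n_nghc)] + [
        f"ind_nhc_{i:03d}" for i in range(n_nhc)
    ]
    labels = {c: (NGHC if c.startswith("ind_nghc") else NHC) for c in chems}
    rng = _rng(config.seed, "independent", zlib.crc32(dataset_id.encode()))
    values = _simulate_matrix(
        config, platform, probe_base[platform.family], truth, [labels[c] for c in chems], rng
    )
    return ExpressionDataset(
        dataset_id=dataset_id,
        platform=platform,
        chemicals=chems,
        labels=labels,
        values=values,
    )
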