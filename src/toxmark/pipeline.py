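"""End-to-end pipeline: curate → data → DEGs → consensus → models → report.

``run_pipeline`` executes the whole study on generated (or user-supplied)
datasets and writes every artifact as TSV/JSON plus a manifest of content
hashes; identical config + seed gives hash-identical outputs.  Stage
failures abort with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from toxmark import degs as degs_mod
from toxmark import robustness as rob_mod
from toxmark.curation import merge_annotations, read_annotations_tsv, write_curation_report
from toxmark.data import feature_matrix, read_dataset_bundle, write_dataset_bundle
from toxmark.errors import StageError, ToxmarkError
from toxmark.estimators import make_classifier, serialize_model
from toxmark.evaluation import DatasetModel, independent_test, loocv, roc_auc, tune
from toxmark.fixtures import fixture_annotations, load_reclassification_fixture
from toxmark.reclassify import verdict_counts, verdict_table, write_verdict_report
from toxmark.simulate import (
    DatasetConfig,
    StudyConfig,
    generate_independent_set,
    generate_study,
)

logger = logging.getLogger("toxmark")

__all__ = ["PipelineConfig", "run_pipeline", "export_report", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run (YAML-loadable)."""

    seed: int = 0
    annotations_path: str | None = None  # default: packaged fixture annotations
    data_dir: str | None = None  # read bundles instead of generating
    dataset_ids: list[str] = field(default_factory=list)  # used with data_dir
    generator: StudyConfig = field(default_factory=StudyConfig)
    p_max: float = 0.05
    fc_min: float = 1.5
    ttest_variant: str = "pooled"
    fc_convention: str = "geometric"
    algorithm: str = "bagging"
    tree_grid: list[int] = field(default_factory=lambda: list(range(5, 51, 5)))
    run_robustness: bool = False
    robustness_dataset: str = "DMC"
    robustness: rob_mod.SubsetPlanConfig = field(default_factory=rob_mod.SubsetPlanConfig)
    run_independent: bool = False
    independent_n_nghc: int = 9
    independent_n_nhc: int = 54
    independent_family: str = "codelink_like"


def load_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    gen_raw = raw.pop("generator", {})
    rob_raw = raw.pop("robustness", {})
    ds_raw = gen_raw.pop("datasets", None)
    gen = StudyConfig(**gen_raw)
    if ds_raw is not None:
        gen.datasets = [DatasetConfig(**d) for d in ds_raw]
    cfg = PipelineConfig(**raw)
    cfg.generator = gen
    cfg.robustness = rob_mod.SubsetPlanConfig(**rob_raw)
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.artifacts: dict[str, dict] = {}

    def add(self, name: str, path: Path) -> None:
        self.artifacts[name] = {
            "path": str(path.relative_to(self.outdir)),
            "sha256": _sha256(path),
        }

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps({"artifacts": self.artifacts}, indent=2, sort_keys=True))
        return path


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except ToxmarkError:
                raise
            except Exception as exc:  # wrap foreign failures with the stage name
                raise StageError(name, str(exc)) from exc
            logger.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir)
    summary: dict = {"seed": config.seed}

    # --- curation ------------------------------------------------------
    try:
        if config.annotations_path is not None:
            annotations = read_annotations_tsv(config.annotations_path)
        else:
            annotations = fixture_annotations()
        curation = merge_annotations(annotations)
    except ToxmarkError as exc:
        raise StageError("curation", str(exc)) from exc
    except OSError as exc:
        raise StageError("curation", str(exc)) from exc
    write_curation_report(curation, outdir / "curation.tsv")
    manifest.add("curation", outdir / "curation.tsv")
    summary["curation_counts"] = curation.counts

    # --- datasets ------------------------------------------------------
    try:
        if config.data_dir is not None:
            datasets = [
                read_dataset_bundle(config.data_dir, ds_id) for ds_id in config.dataset_ids
            ]
            truth = None
        else:
            config.generator.seed = config.seed
            study = generate_study(config.generator)
            datasets = study.datasets
            truth = sorted(study.truth)
            for ds in datasets:
                for name, path in write_dataset_bundle(ds, outdir / "data").items():
                    manifest.add(f"data/{ds.dataset_id}/{name}", path)
    except ToxmarkError as exc:
        raise StageError("data", str(exc)) from exc
    summary["datasets"] = {ds.dataset_id: ds.class_counts() for ds in datasets}
    if truth is not None:
        summary["planted_markers"] = truth

    # --- differential expression + consensus ---------------------------
    thresholds = degs_mod.DegThresholds(config.p_max, config.fc_min)
    deg_results = {}
    try:
        for ds in datasets:
            res = degs_mod.identify_degs(
                ds, thresholds, variant=config.ttest_variant, convention=config.fc_convention
            )
            deg_results[ds.dataset_id] = res
            path = outdir / f"degs.{ds.dataset_id}.tsv"
            res.table.to_csv(path, sep="\t", index=False)
            manifest.add(f"degs/{ds.dataset_id}", path)
        consensus = degs_mod.consensus_intersection(
            [deg_results[ds.dataset_id].gene_degs for ds in datasets],
            [ds.dataset_id for ds in datasets],
        )
    except ToxmarkError as exc:
        raise StageError("degs", str(exc)) from exc
    summary["deg_counts"] = {k: len(v.gene_degs) for k, v in deg_results.items()}
    summary["consensus_genes"] = sorted(consensus.genes)
    cons_path = outdir / "consensus.tsv"
    pd.DataFrame(
        {
            "gene": sorted(consensus.genes),
            "datasets_supporting": [
                ";".join(ds for ds, s in consensus.provenance.items() if g in s)
                for g in sorted(consensus.genes)
            ],
        }
    ).to_csv(cons_path, sep="\t", index=False)
    manifest.add("consensus", cons_path)
    venn_path = outdir / "venn_counts.json"
    venn_path.write_text(json.dumps(consensus.venn_counts(), indent=2, sort_keys=True))
    manifest.add("venn_counts", venn_path)

    markers = sorted(consensus.genes)
    models: dict[str, DatasetModel] = {}
    if markers:
        # --- per-dataset tuning + LOOCV --------------------------------
        try:
            summary["models"] = {}
            for ds in datasets:
                fm = feature_matrix(ds, markers)
                proto = make_classifier(config.algorithm)
                if config.algorithm in ("bagging", "boosting", "random_forest"):
                    tuned = tune(fm, proto, "n_trees", config.tree_grid, config.seed)
                elif config.algorithm == "knn":
                    tuned = tune(fm, proto, "k", [1, 3, 5], config.seed)
                else:
                    tuned = None
                if tuned is not None:
                    proto = proto.set_params(
                        **{"n_trees" if config.algorithm != "knn" else "k": tuned.best}
                    )
                scores = loocv(fm, proto, config.seed)
                roc = roc_auc(scores)
                final = proto.fit(fm.values, fm.label_array)
                models[ds.dataset_id] = DatasetModel(
                    ds.dataset_id, ds.platform.family, markers, final
                )
                model_path = outdir / f"model.{ds.dataset_id}.json"
                model_path.write_text(json.dumps(serialize_model(final), sort_keys=True))
                manifest.add(f"model/{ds.dataset_id}", model_path)
                roc_path = outdir / f"roc.{ds.dataset_id}.tsv"
                pd.DataFrame(roc.curve, columns=["fpr", "tpr"]).to_csv(
                    roc_path, sep="\t", index=False
                )
                manifest.add(f"roc/{ds.dataset_id}", roc_path)
                summary["models"][ds.dataset_id] = {
                    "algorithm": config.algorithm,
                    "tuned": None if tuned is None else {str(k): v for k, v in tuned.grid.items()},
                    "best_param": None if tuned is None else tuned.best,
                    "loocv_auc": roc.auc,
                }
        except ToxmarkError as exc:
            raise StageError("train", str(exc)) from exc

        # --- robustness (optional) -------------------------------------
        if config.run_robustness:
            try:
                ds = next(d for d in datasets if d.dataset_id == config.robustness_dataset)
                fm = feature_matrix(ds, markers)
                plan_cfg = config.robustness
                plan_cfg.seed = config.seed
                plan = rob_mod.sample_constrained_subsets(fm.chemicals, fm.labels, plan_cfg)
                rob_mod.verify_plan(plan, fm.labels, plan_cfg)
                est = make_classifier(config.algorithm)
                summ = rob_mod.robustness_auc(fm, markers, plan, est, config.seed)
                summary["robustness"] = {
                    "dataset": ds.dataset_id,
                    "mean_auc": summ.mean,
                    "sd_auc": summ.sd,
                    "n_subsets": len(summ.aucs),
                }
                rob_path = outdir / "robustness.json"
                rob_path.write_text(
                    json.dumps({"aucs": summ.aucs, "mean": summ.mean, "sd": summ.sd}, indent=2)
                )
                manifest.add("robustness", rob_path)
            except (ToxmarkError, StopIteration) as exc:
                raise StageError("robustness", str(exc)) from exc

        # --- independent test (optional) -------------------------------
        if config.run_independent and config.data_dir is None:
            try:
                fam = config.independent_family
                platform = study.platforms[fam]
                ind = generate_independent_set(
                    config.generator,
                    platform,
                    n_nghc=config.independent_n_nghc,
                    n_nhc=config.independent_n_nhc,
                )
                fm_ind = feature_matrix(ind, markers)
                results, skipped = independent_test(models, fm_ind)
                summary["independent_test"] = {
                    "aucs": {k: r.auc for k, r in results.items()},
                    "skipped": skipped,
                }
            except ToxmarkError as exc:
                raise StageError("independent_test", str(exc)) from exc
    else:
        summary["models"] = {}
        summary["skipped"] = "no consensus genes; model stages skipped"

    # --- reclassification ----------------------------------------------
    try:
        call_table = load_reclassification_fixture()
        verdicts = verdict_table(call_table)
        verdict_path = outdir / "verdicts.tsv"
        write_verdict_report(call_table, verdict_path)
        manifest.add("verdicts", verdict_path)
        summary["verdict_counts"] = verdict_counts(verdicts)
    except ToxmarkError as exc:
        raise StageError("reclassify", str(exc)) from exc

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.add("summary", summary_path)
    manifest_path = manifest.write()
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return {"artifacts": manifest.artifacts}


def export_report(outdir) -> str:
    """Render the run summary as a human-readable text report (idempotent)."""
    outdir = Path(outdir)
    summary_path = outdir / "summary.json"
    warnings_list = []
    if not summary_path.exists():
        return "No summary.json found; run the pipeline first.\n"
    summary = json.loads(summary_path.read_text())
    lines = ["# toxmark run report", ""]
    lines.append(f"seed: {summary.get('seed')}")
    if "curation_counts" in summary:
        lines.append(f"curation: {summary['curation_counts']}")
    if "deg_counts" in summary:
        lines.append("DEG counts per dataset:")
        for ds, n in sorted(summary["deg_counts"].items()):
            lines.append(f"  {ds}: {n}")
    genes = summary.get("consensus_genes", [])
    lines.append(f"consensus genes ({len(genes)}): {', '.join(genes) if genes else 'none'}")
    if not genes:
        lines.append("model stages skipped (empty consensus).")
    if summary.get("models"):
        lines.append("per-dataset models (tuned by LOOCV AUC):")
    for ds, info in sorted(summary.get("models", {}).items()):
        lines.append(
            f"  {ds}: {info['algorithm']}"
            + (f" (best={info['best_param']})" if info.get("best_param") is not None else "")
            + f", LOOCV AUC = {info['loocv_auc']:.3f}"
        )
    if "robustness" in summary:
        r = summary["robustness"]
        lines.append(
            f"robustness ({r['dataset']}, {r['n_subsets']} subsets): "
            f"AUC {r['mean_auc']:.3f} ± {r['sd_auc']:.3f}"
        )
    if "independent_test" in summary:
        it = summary["independent_test"]
        for ds, auc in sorted(it["aucs"].items()):
            lines.append(f"independent test, model {ds}: AUC {auc:.3f}")
        if it.get("skipped"):
            lines.append(f"independent test skipped models: {', '.join(it['skipped'])}")
    if "verdict_counts" in summary:
        lines.append(f"reclassification verdicts: {summary['verdict_counts']}")
    for w in warnings_list:
        lines.append(f"WARNING: {w}")
    return "\n".join(lines) + "\n"
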