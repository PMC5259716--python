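"""Merge chemical carcinogenicity labels from multiple literature sources.

Chemicals used for biomarker discovery must have an uncontested
non-genotoxic-hepatocarcinogen (NGHC) or non-hepatocarcinogen (NHC) label.
This module merges per-source annotations into one record per chemical,
quarantines chemicals whose sources disagree (NGHC vs NHC) for later
model-based reclassification, and excludes hepatocarcinogens acting through
genotoxic mechanisms only.  A hepatocarcinogen with both genotoxic and
non-genotoxic mechanism annotations counts as NGHC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from toxmark.errors import DataIntegrityError, InvalidNameError

__all__ = [
    "Label",
    "Status",
    "SourceAnnotation",
    "ChemicalRecord",
    "CurationResult",
    "canonicalize_name",
    "merge_annotations",
    "read_annotations_tsv",
    "write_curation_report",
]


class Label(str, Enum):
    """Per-source carcinogenicity label."""

    NGHC = "NGHC"
    NHC = "NHC"
    GENOTOXIC_ONLY = "GENOTOXIC_ONLY"


class Status(str, Enum):
    """Merged status of a chemical after curation."""

    NGHC = "NGHC"
    NHC = "NHC"
    INCONSISTENT = "INCONSISTENT"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class SourceAnnotation:
    chemical_name: str
    source_id: str
    label: Label


@dataclass
class ChemicalRecord:
    chemical_name: str
    labels_by_source: dict[str, Label]
    status: Status
    doses_by_dataset: dict[str, float] = field(default_factory=dict)


@dataclass
class CurationResult:
    """Partition of the input chemicals into consistent / quarantined / excluded."""

    consistent: list[ChemicalRecord]
    quarantined: list[ChemicalRecord]
    excluded: list[ChemicalRecord]

    def all_records(self) -> list[ChemicalRecord]:
        return [*self.consistent, *self.quarantined, *self.excluded]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "consistent": len(self.consistent),
            "quarantined": len(self.quarantined),
            "excluded": len(self.excluded),
        }


_DASHES = {"‐": "-", "‑": "-", "‒": "-", "–": "-", "—": "-"}


def canonicalize_name(raw: str) -> str:
    """Canonicalize a chemical name: case-fold, collapse whitespace, unify dashes.

    Idempotent.  No synonym or CAS-number resolution is attempted; the
    curated lists are name-keyed.
    """
    if raw is None or not str(raw).strip():
        raise InvalidNameError("chemical name is empty or whitespace-only")
    s = str(raw).strip().casefold()
    for bad, good in _DASHES.items():
        s = s.replace(bad, good)
    s = re.sub(r"\s+", " ", s)
    s = re.sub(r"\s*-\s*", "-", s)
    return s


def _merge_one(name: str, labels_by_source: dict[str, Label]) -> ChemicalRecord:
    labels = set(labels_by_source.values())
    if Label.NGHC in labels and Label.NHC in labels:
        status = Status.INCONSISTENT
    elif labels == {Label.GENOTOXIC_ONLY}:
        status = Status.EXCLUDED
    elif Label.GENOTOXIC_ONLY in labels and Label.NHC in labels:
        # genotoxic-hepatocarcinogen + non-carcinogen from different sources
        # cannot both be right; surfaced rather than silently resolved
        raise DataIntegrityError(
            f"chemical {name!r} labelled both GENOTOXIC_ONLY and NHC"
        )
    elif Label.NGHC in labels:
        # possibly mixed genotoxic/non-genotoxic mechanisms -> NGHC
        status = Status.NGHC
    else:
        status = Status.NHC
    return ChemicalRecord(name, dict(labels_by_source), status)


def merge_annotations(annotations: Iterable[SourceAnnotation]) -> CurationResult:
    """Merge per-source annotations into one labelled record per chemical.

    Chemicals annotated both NGHC and NHC are quarantined as INCONSISTENT
    (regardless of any additional labels); chemicals whose only label is
    GENOTOXIC_ONLY are excluded; NGHC coexisting with GENOTOXIC_ONLY
    resolves to NGHC.  Raises :class:`DataIntegrityError` when the same
    (chemical, source) pair carries two different labels, or when
    GENOTOXIC_ONLY coexists with NHC without an NGHC label.
    """
    by_chem: dict[str, dict[str, Label]] = {}
    for ann in annotations:
        name = canonicalize_name(ann.chemical_name)
        label = Label(ann.label)
        sources = by_chem.setdefault(name, {})
        if ann.source_id in sources and sources[ann.source_id] != label:
            raise DataIntegrityError(
                f"source {ann.source_id!r} assigns two labels to {name!r}"
            )
        sources[ann.source_id] = label

    result = CurationResult([], [], [])
    for name in sorted(by_chem):
        rec = _merge_one(name, by_chem[name])
        if rec.status in (Status.NGHC, Status.NHC):
            result.consistent.append(rec)
        elif rec.status is Status.INCONSISTENT:
            result.quarantined.append(rec)
        else:
            result.excluded.append(rec)
    return result


def read_annotations_tsv(path) -> list[SourceAnnotation]:
    """Read annotations from a TSV with columns chemical, source, label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"chemical", "source", "label"} - set(df.columns)
    if missing:
        raise DataIntegrityError(f"annotation TSV lacks columns: {sorted(missing)}")
    return [
        SourceAnnotation(row.chemical, row.source, Label(row.label))
        for row in df.itertuples(index=False)
    ]


def write_curation_report(result: CurationResult, path, dataset_ids: list[str] | None = None) -> None:
    """Write the merged records as a TSV report.

    One row per chemical with its status, semicolon-joined per-source
    labels, and one dose column per dataset (blank where the chemical has
    no data in that dataset).
    """
    if dataset_ids is None:
        seen: dict[str, None] = {}
        for rec in result.all_records():
            for ds in rec.doses_by_dataset:
                seen.setdefault(ds, None)
        dataset_ids = sorted(seen)
    rows = []
    for rec in result.all_records():
        row: dict[str, object] = {
            "chemical": rec.chemical_name,
            "status": rec.status.value,
            "labels_by_source": ";".join(
                f"{src}={lab.value}" for src, lab in sorted(rec.labels_by_source.items())
            ),
        }
        for ds in dataset_ids:
            row[f"dose_{ds}"] = rec.doses_by_dataset.get(ds, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def records_by_name(result: CurationResult) -> Mapping[str, ChemicalRecord]:
    return {rec.chemical_name: rec for rec in result.all_records()}
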