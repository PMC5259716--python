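"""Packaged worked example: the 16 controversially classified chemicals.

Sixteen chemicals carry both NGHC and NHC labels in the curated literature
sources.  This module ships, as plain in-code tables, (a) their per-source
labels and per-dataset maximum-tolerated doses (mg/kg), and (b) the
per-dataset NGHC/NHC calls produced by the bagging decision-tree models of
the published study, so the majority-vote reclassification rule can be
exercised and checked end-to-end without any external download.

Caveat on transcription: for the five chemicals decided jointly by the
DMC, GSE8858 and TG-GATEs models the published account reports only the
aggregate NHC outcome; all three calls are recorded here as NHC (the only
transcription consistent with the reported unanimity).  This assumption is
flagged in ``CALL_TABLE_NOTES``.
"""

from __future__ import annotations

from toxmark.curation import (
    ChemicalRecord,
    CurationResult,
    Label,
    SourceAnnotation,
    Status,
    merge_annotations,
)

__all__ = [
    "DATASET_IDS",
    "build_paper_fixture",
    "fixture_annotations",
    "load_reclassification_fixture",
    "CALL_TABLE_NOTES",
]

DATASET_IDS = ["DMA", "DMC", "GSE8858", "TG-GATEs"]

# chemical -> (doses per dataset; None = no expression data in that dataset)
_DOSES: dict[str, tuple[float | None, float | None, float | None, float | None]] = {
    "acetaminophen": (None, 972, 972, 1000),
    "beta-estradiol": (150, 150, 150, None),
    "carbamazepine": (490, 490, 490, 300),
    "diazepam": (710, 710, 710, 250),
    "diethylstilbestrol": (2.8, 280, 280, None),
    "ethanol": (None, 6000, 6000, 4000),
    "ethionamide": (None, None, None, 250),
    "griseofulvin": (None, 2500, 2500, 1000),
    "haloperidol": (None, None, None, 30),
    "isoniazid": (None, 79, 79, 2000),
    "rifampin": (None, None, None, 200),
    "simvastatin": (1200, 1200, 1200, 400),
    "sulfasalazine": (None, None, None, 1000),
    "tamoxifen": (None, 64, 64, 60),
    "tannic acid": (None, None, None, 1000),
    "triamterene": (None, None, None, 150),
}

# chemical -> (NGHC-labelling source keys, NHC-labelling source keys)
_SOURCES: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "acetaminophen": (("fielden_a",), ("uehara",)),
    "beta-estradiol": (("fielden_a",), ("liu",)),
    "carbamazepine": (("fielden_a",), ("uehara",)),
    "diazepam": (("yamada",), ("fielden_b",)),
    "diethylstilbestrol": (("fielden_a",), ("liu",)),
    "ethanol": (("fielden_a",), ("uehara",)),
    "ethionamide": (("yamada",), ("uehara",)),
    "griseofulvin": (("yamada", "liu"), ("uehara",)),
    "haloperidol": (("yamada",), ("uehara",)),
    "isoniazid": (("liu",), ("uehara",)),
    "rifampin": (("uehara",), ("yamada",)),
    "simvastatin": (("fielden_a",), ("uehara",)),
    "sulfasalazine": (("yamada",), ("uehara",)),
    "tamoxifen": (("yamada",), ("uehara",)),
    "tannic acid": (("yamada",), ("uehara",)),
    "triamterene": (("yamada",), ("uehara",)),
}

# chemical -> per-dataset hard call of the published per-dataset models;
# keys restricted to datasets where the chemical has expression data.
_CALLS: dict[str, dict[str, str]] = {
    "beta-estradiol": {"DMA": "NGHC", "DMC": "NGHC", "GSE8858": "NGHC"},
    "diethylstilbestrol": {"DMA": "NGHC", "DMC": "NGHC", "GSE8858": "NGHC"},
    "rifampin": {"TG-GATEs": "NGHC"},
    "ethionamide": {"TG-GATEs": "NHC"},
    "haloperidol": {"TG-GATEs": "NHC"},
    "sulfasalazine": {"TG-GATEs": "NHC"},
    "tannic acid": {"TG-GATEs": "NHC"},
    "triamterene": {"TG-GATEs": "NHC"},
    "acetaminophen": {"DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
    "ethanol": {"DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
    "griseofulvin": {"DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
    "isoniazid": {"DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
    "tamoxifen": {"DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
    "simvastatin": {"DMA": "NHC", "DMC": "NHC", "GSE8858": "NHC", "TG-GATEs": "NGHC"},
    "carbamazepine": {"DMA": "NHC", "DMC": "NGHC", "GSE8858": "NGHC", "TG-GATEs": "NHC"},
    "diazepam": {"DMA": "NGHC", "DMC": "NGHC", "GSE8858": "NHC", "TG-GATEs": "NHC"},
}

CALL_TABLE_NOTES = {
    "three_dataset_nhc_assumption": (
        "acetaminophen, ethanol, griseofulvin, isoniazid and tamoxifen are "
        "recorded as NHC in all three of DMC, GSE8858 and TG-GATEs; only the "
        "aggregate NHC outcome is published, so a dissenting minority call "
        "cannot be excluded."
    )
}


def fixture_annotations() -> list[SourceAnnotation]:
    """Per-source annotations for the 16 inconsistently classified chemicals."""
    anns = []
    for chem, (nghc_srcs, nhc_srcs) in _SOURCES.items():
        for src in nghc_srcs:
            anns.append(SourceAnnotation(chem, src, Label.NGHC))
        for src in nhc_srcs:
            anns.append(SourceAnnotation(chem, src, Label.NHC))
    return anns


def build_paper_fixture() -> tuple[CurationResult, dict[str, dict[str, str]]]:
    """Build the packaged 16-chemical fixture.

    Returns a :class:`CurationResult` whose ``quarantined`` list holds the
    16 chemicals with their per-dataset doses, together with the call table
    mapping chemical -> dataset -> NGHC/NHC call.
    """
    result = merge_annotations(fixture_annotations())
    assert not result.consistent and not result.excluded
    for rec in result.quarantined:
        doses = _DOSES[rec.chemical_name]
        rec.doses_by_dataset = {
            ds: dose for ds, dose in zip(DATASET_IDS, doses) if dose is not None
        }
    return result, load_reclassification_fixture()


def load_reclassification_fixture() -> dict[str, dict[str, str]]:
    """Call table for the 16 quarantined chemicals (chemical -> dataset -> call).

    Call availability matches dose availability exactly: a model can only be
    applied where the chemical was profiled.
    """
    table = {chem: dict(calls) for chem, calls in _CALLS.items()}
    for chem, calls in table.items():
        avail = {ds for ds, dose in zip(DATASET_IDS, _DOSES[chem]) if dose is not None}
        assert set(calls) == avail, chem
    return table


def quarantined_records() -> list[ChemicalRecord]:
    result, _ = build_paper_fixture()
    assert all(rec.status is Status.INCONSISTENT for rec in result.quarantined)
    return result.quarantined
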