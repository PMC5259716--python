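"""Majority-vote reclassification of quarantined chemicals.

A quarantined chemical (conflicting NGHC/NHC literature labels) is scored
by each dataset's fitted model wherever its expression profile exists; the
per-dataset hard calls are then aggregated into a three-way verdict: NGHC
when strictly more models call NGHC, NHC when strictly more call NHC, and
UNDEFINED on a tie.  Dataset identity carries no weight — only the call
multiset matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from toxmark.data import NGHC, NHC
from toxmark.errors import ConfigError
from toxmark.fixtures import DATASET_IDS, load_reclassification_fixture

__all__ = [
    "Verdict",
    "call_chemical",
    "majority_verdict",
    "verdict_table",
    "write_verdict_report",
    "load_reclassification_fixture",
]

UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class Verdict:
    chemical: str
    verdict: str  # NGHC | NHC | UNDEFINED
    n_nghc_calls: int
    n_nhc_calls: int


def call_chemical(
    models: dict[str, object],
    profiles: dict[str, np.ndarray],
) -> dict[str, str]:
    """Per-dataset hard calls for one chemical.

    ``profiles`` maps dataset id -> feature vector aligned with that
    dataset's model (NaN allowed); datasets without a profile are omitted
    from the result.  A score above 0.5 calls NGHC; 0.5 or below calls NHC
    (no positive hazard call on a tie).
    """
    if not profiles:
        raise ConfigError("no expression profile available in any dataset")
    unknown = set(profiles) - set(models)
    if unknown:
        raise ConfigError(f"profiles reference unknown datasets: {sorted(unknown)}")
    calls: dict[str, str] = {}
    for ds_id, profile in profiles.items():
        row = np.asarray(profile, dtype=float).reshape(1, -1)
        score = float(models[ds_id].predict_score(row)[0])
        calls[ds_id] = NGHC if score > 0.5 else NHC
    return calls


def majority_verdict(calls: dict[str, str], chemical: str = "") -> Verdict:
    """Aggregate per-dataset calls into a three-way verdict by majority."""
    if not calls:
        raise ConfigError("verdict needs at least one call")
    values = list(calls.values())
    bad = [v for v in values if v not in (NGHC, NHC)]
    if bad:
        raise ConfigError(f"calls must be NGHC or NHC, got {bad}")
    n_pos = values.count(NGHC)
    n_neg = values.count(NHC)
    if n_pos > n_neg:
        verdict = NGHC
    elif n_neg > n_pos:
        verdict = NHC
    else:
        verdict = UNDEFINED
    return Verdict(chemical, verdict, n_pos, n_neg)


def verdict_table(call_table: dict[str, dict[str, str]]) -> list[Verdict]:
    """Verdicts for every chemical of a call table, sorted by name."""
    return [
        majority_verdict(call_table[chem], chemical=chem) for chem in sorted(call_table)
    ]


def verdict_counts(verdicts: list[Verdict]) -> dict[str, int]:
    out = {NGHC: 0, NHC: 0, UNDEFINED: 0}
    for v in verdicts:
        out[v.verdict] += 1
    return out


def write_verdict_report(
    call_table: dict[str, dict[str, str]],
    path,
    dataset_ids: list[str] | None = None,
) -> pd.DataFrame:
    """TSV report: chemical, per-dataset call (NA where no data), verdict, counts."""
    if dataset_ids is None:
        dataset_ids = DATASET_IDS
    rows = []
    for v in verdict_table(call_table):
        row: dict[str, object] = {"chemical": v.chemical}
        for ds in dataset_ids:
            row[ds] = call_table[v.chemical].get(ds, "NA")
        row.update(
            verdict=v.verdict, n_nghc_calls=v.n_nghc_calls, n_nhc_calls=v.n_nhc_calls
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
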