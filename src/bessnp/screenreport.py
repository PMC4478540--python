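"""Marker-screening (KASP assay) result tables and validation rates.

Parses screening tables of the kind used to choose mapping parameters: for
each marker, the wet-lab assay outcome (Good / Bad / Maybe), whether the
marker was identified by each mapping-parameter iteration, whether the
homeo-SNP filter retained or removed it, and the resulting per-iteration
final outcome. Validation rates summarise how many in-silico markers
survive empirical testing.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

KASP_RESULTS = {"Good", "Bad", "Maybe"}
SECTIONS = {"transcriptome", "non-transcriptome"}
REMOVALS = {"Retain", "Remove", "NA"}
FINALS = {"Good", "Bad", "NA"}

_COLUMNS = [
    "marker",
    "section",
    "kasp_result",
    "identified_iter1",
    "identified_iter2",
    "removal_iter1",
    "removal_iter2",
    "final_iter1",
    "final_iter2",
]


@dataclass(frozen=True)
class ScreeningRecord:
    marker: str
    section: str
    kasp_result: str
    identified_iter1: bool
    identified_iter2: bool
    removal_iter1: str
    removal_iter2: str
    final_iter1: str
    final_iter2: str


class TableFormatError(ValueError):
    pass


def load_table(path: str | Path) -> list[ScreeningRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size <= 1:
        return []
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing columns: {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = ScreeningRecord(
            marker=row.marker,
            section=row.section,
            kasp_result=row.kasp_result,
            identified_iter1=_flag(row.identified_iter1, i),
            identified_iter2=_flag(row.identified_iter2, i),
            removal_iter1=row.removal_iter1,
            removal_iter2=row.removal_iter2,
            final_iter1=row.final_iter1,
            final_iter2=row.final_iter2,
        )
        for value, allowed, what in (
            (rec.section, SECTIONS, "section"),
            (rec.kasp_result, KASP_RESULTS, "kasp_result"),
            (rec.removal_iter1, REMOVALS, "removal_iter1"),
            (rec.removal_iter2, REMOVALS, "removal_iter2"),
            (rec.final_iter1, FINALS, "final_iter1"),
            (rec.final_iter2, FINALS, "final_iter2"),
        ):
            if value not in allowed:
                raise TableFormatError(
                    f"row {i}: invalid {what} value {value!r}"
                )
        for it in ("1", "2"):
            if getattr(rec, f"final_iter{it}") != "NA" and not (
                getattr(rec, f"identified_iter{it}")
                and getattr(rec, f"removal_iter{it}") == "Retain"
            ):
                raise TableFormatError(
                    f"row {i}: final_iter{it} set but marker not identified+retained"
                )
        records.append(rec)
    return records


def packaged_table() -> list[ScreeningRecord]:
    """The bundled interspecific screening table (32 markers)."""
    path = importlib.resources.files("bessnp") / "data" / "kasp_screen_barbadense.tsv"
    return load_table(str(path))


def simple_rate(good: int, total: int) -> float:
    """100*good/total to 1 decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= good <= total:
        raise ValueError("good must be in [0, total]")
    return round(100.0 * good / total, 1)


def screening_rates(records: Sequence[ScreeningRecord]) -> dict[str, float | int]:
    """Overall good rate and, among good markers, the section shares."""
    if not records:
        return {"n": 0, "good_n": 0, "good_pct": float("nan")}
    good = [r for r in records if r.kasp_result == "Good"]
    good_tr = [r for r in good if r.section == "transcriptome"]
    out: dict[str, float | int] = {
        "n": len(records),
        "good_n": len(good),
        "good_pct": simple_rate(len(good), len(records)),
    }
    if good:
        out["good_transcriptome_n"] = len(good_tr)
        out["good_transcriptome_pct"] = simple_rate(len(good_tr), len(good))
        out["good_nontranscriptome_n"] = len(good) - len(good_tr)
        out["good_nontranscriptome_pct"] = simple_rate(
            len(good) - len(good_tr), len(good)
        )
    return out


def iteration_success(
    records: Sequence[ScreeningRecord], iteration: int
) -> dict[str, float | int]:
    """Post-filter success rate: Good / (Good + Bad) final results of an
    iteration; 'Maybe' assays carry final result NA and are excluded."""
    if iteration not in (1, 2):
        raise ValueError("iteration must be 1 or 2")
    finals = [getattr(r, f"final_iter{iteration}") for r in records]
    good = sum(f == "Good" for f in finals)
    bad = sum(f == "Bad" for f in finals)
    if good + bad == 0:
        return {"good_n": 0, "bad_n": 0, "success_pct": float("nan")}
    return {
        "good_n": good,
        "bad_n": bad,
        "success_pct": simple_rate(good, good + bad),
    }


def _flag(value: str, row: int) -> bool:
    if value in ("Yes", "yes", "1", "True", "true"):
        return True
    if value in ("No", "no", "0", "False", "false"):
        return False
    raise TableFormatError(f"row {row}: invalid yes/no value {value!r}")
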